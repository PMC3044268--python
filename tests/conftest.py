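import random

import pytest

import genedup as gd
from genedup import simulate


@pytest.fixture
def rng():
    return random.Random(20260926)


@pytest.fixture
def three_triples_instance():
    """The three possible rooted triples on {a,b,c}: any species tree
    conflicts with exactly two of them, so the optimum is 2."""
    trees = tuple(gd.parse_newick(s) for s in ["((a,b),c);", "((a,c),b);", "((b,c),a);"])
    return gd.ProblemInstance(gene_trees=trees)


@pytest.fixture
def lifted_three_triples_instance():
    """The same conflict lifted to four taxa (taxon d appended outside),
    which routes through the ILP instead of the tiny-n brute-force path."""
    trees = tuple(
        gd.parse_newick(s)
        for s in ["(((a,b),c),d);", "(((a,c),b),d);", "(((b,c),a),d);"]
    )
    return gd.ProblemInstance(gene_trees=trees)


def random_gene_tree(S, rng, p_dup=0.25, p_loss=0.3, min_leaves=3):
    """A simulated gene family over S with at least ``min_leaves`` leaves."""
    while True:
        g, events, _ = simulate.simulate_gene_tree(S, p_dup, p_loss, rng)
        if g.n_leaves >= min_leaves:
            return g, events
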