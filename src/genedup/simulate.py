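"""Synthetic species trees and duplication/loss gene families.

The generator draws a species tree uniformly at random over rooted binary
topologies, then grows each gene family by a depth-first walk over the
species tree: at every visited vertex at most one event happens -- a
duplication (the whole current subtree is copied, and the walk continues
into both copies) with probability ``p_dup``, a loss (the current subtree
is cut) with probability ``p_loss``, or nothing.  The defaults, 0.25
duplications and 0.3 losses per visited vertex, produce gene families with
realistic size spread and duplication signal for a handful to a dozen taxa.

Every event is logged, which gives an independent bookkeeping check: with
no losses, the duplication cost of a simulated gene tree against the true
species tree equals exactly the number of logged duplications; with losses
it is bounded above by the number of duplications in which both copies kept
at least one surviving leaf (a surviving duplication vertex whose two copies
retain disjoint species sets is indistinguishable from a speciation).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .tree_core import RootedTree


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset."""

    n: int  # taxa in the species tree
    k: int  # gene families
    p_dup: float = 0.25  # duplication probability per visited vertex
    p_loss: float = 0.3  # loss probability per visited vertex
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least 2 taxa")
        if self.k < 1:
            raise ValueError("need at least 1 gene family")
        if self.p_dup < 0 or self.p_loss < 0 or self.p_dup + self.p_loss > 1:
            raise ValueError("require p_dup >= 0, p_loss >= 0, p_dup + p_loss <= 1")


@dataclass
class Event:
    kind: str  # "duplication" | "loss"
    species_vertex: int  # vertex of S whose subtree the event hit
    survived: bool = True  # duplication only: both copies kept >= 1 leaf


@dataclass
class SimulatedDataset:
    species_tree: RootedTree
    gene_trees: list[RootedTree]
    event_logs: list[list[Event]]
    config: SimulationConfig
    regenerated: int = 0  # families redrawn because < 3 leaves survived
    root_redraws: int = 0  # walks redrawn because the whole family was lost

    def surviving_duplications(self, i: int) -> int:
        return sum(
            1 for e in self.event_logs[i] if e.kind == "duplication" and e.survived
        )


def random_species_tree(n: int, rng: random.Random) -> RootedTree:
    """A species tree drawn uniformly over the (2n-3)!! rooted binary
    topologies, leaves labeled t1..tn.

    Taxa are attached one at a time at a uniformly chosen vertex (the new
    leaf becomes that vertex's sibling); at step i there are 2i-3 choices,
    so every topology has probability 1/(2n-3)!!.
    """
    if n < 2:
        raise ValueError("need at least 2 taxa")
    tree = "t1"
    for i in range(2, n + 1):
        size = 2 * (i - 1) - 1  # vertices of the current tree
        pos = rng.randrange(size)
        tree = _attach_at(tree, f"t{i}", pos)
    return RootedTree.from_nested(tree)


def _size(tree) -> int:
    if not isinstance(tree, tuple):
        return 1
    return 1 + _size(tree[0]) + _size(tree[1])


def _attach_at(tree, leaf: str, pos: int):
    """Attach ``leaf`` as sibling of the ``pos``-th vertex in preorder."""
    if pos == 0:
        return (tree, leaf)
    left, right = tree  # pos > 0 implies an internal vertex
    ls = _size(left)
    if pos - 1 < ls:
        return (_attach_at(left, leaf, pos - 1), right)
    return (left, _attach_at(right, leaf, pos - 1 - ls))


def simulate_gene_tree(
    S: RootedTree,
    p_dup: float,
    p_loss: float,
    rng: random.Random,
    max_root_redraws: int = 1000,
) -> tuple[RootedTree, list[Event], int]:
    """Grow one gene family along S by the depth-first event walk.

    Returns the gene tree (leaves labeled by species; labels may repeat),
    the event log, and the number of times the walk was redrawn because a
    loss wiped out the entire family.  Degree-2 vertices left by losses are
    suppressed, so the result is always full binary.
    """
    redraws = 0
    while True:
        events: list[Event] = []
        nested = _walk(S, S.root, p_dup, p_loss, rng, events)
        if nested is not None:
            return RootedTree.from_nested(nested), events, redraws
        redraws += 1
        if redraws > max_root_redraws:  # pragma: no cover - p_loss near 1
            raise RuntimeError("loss rate too high: the whole family keeps dying")


def _walk(S: RootedTree, v: int, p_dup: float, p_loss: float, rng, events):
    """Visit the gene-tree vertex tracking species vertex ``v``; returns the
    surviving nested subtree or None if everything below was lost."""
    r = rng.random()
    if r < p_dup:
        ev = Event("duplication", v)
        events.append(ev)
        a = _walk(S, v, p_dup, p_loss, rng, events)
        b = _walk(S, v, p_dup, p_loss, rng, events)
        ev.survived = a is not None and b is not None
        if a is None:
            return b
        if b is None:
            return a
        return (a, b)
    if r < p_dup + p_loss:
        events.append(Event("loss", v))
        return None
    if S.is_leaf(v):
        return S.label(v)
    ca, cb = S.children(v)
    a = _walk(S, ca, p_dup, p_loss, rng, events)
    b = _walk(S, cb, p_dup, p_loss, rng, events)
    if a is None:
        return b  # degree-2 vertex suppressed
    if b is None:
        return a
    return (a, b)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """One species tree and ``k`` gene families, reproducible from the seed.

    Families with fewer than three surviving leaves carry no triple signal
    and are redrawn (count recorded in ``regenerated``).
    """
    rng = random.Random(config.seed)
    S = random_species_tree(config.n, rng)
    gene_trees: list[RootedTree] = []
    logs: list[list[Event]] = []
    regenerated = 0
    root_redraws = 0
    while len(gene_trees) < config.k:
        g, events, redraws = simulate_gene_tree(S, config.p_dup, config.p_loss, rng)
        root_redraws += redraws
        if g.n_leaves < 3:
            regenerated += 1
            continue
        gene_trees.append(g)
        logs.append(events)
    return SimulatedDataset(
        species_tree=S,
        gene_trees=gene_trees,
        event_logs=logs,
        config=config,
        regenerated=regenerated,
        root_redraws=root_redraws,
    )
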