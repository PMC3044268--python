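"""Exhaustive gene-duplication solver: the ground-truth oracle.

Enumerates every rooted binary topology on the taxon set -- there are
(2n-3)!! of them -- and scores each against the gene-tree set.  Correctness
is trivially auditable, which is the whole point: the ILP solver is checked
against this module on small instances.  Guarded at n <= 9 (2,027,025
topologies); beyond that the double-factorial growth makes exhaustion
pointless.
"""

from __future__ import annotations

from typing import Iterable, Iterator

from .reconcile import ProblemInstance, total_dup_cost
from .tree_core import RootedTree

MAX_TAXA = 9


def _n_topologies(n: int) -> int:
    """(2n-3)!! rooted binary topologies on n labeled leaves."""
    out = 1
    for i in range(2, n + 1):
        out *= 2 * i - 3
    return out


def _insertions(tree, leaf: str) -> Iterator:
    """All ways to attach ``leaf`` on an edge of the nested-tuple ``tree``,
    including above the root; yields one tree per vertex of ``tree``."""
    yield (tree, leaf)
    if isinstance(tree, tuple):
        left, right = tree
        for nl in _insertions(left, leaf):
            yield (nl, right)
        for nr in _insertions(right, leaf):
            yield (left, nr)


def _nested_topologies(taxa: tuple[str, ...]) -> Iterator:
    if len(taxa) == 1:
        yield taxa[0]
        return
    for sub in _nested_topologies(taxa[:-1]):
        yield from _insertions(sub, taxa[-1])


def all_species_trees(taxa: Iterable[str]) -> Iterator[RootedTree]:
    """Yield every rooted binary topology on the given labels exactly once,
    in a deterministic order (recursive edge insertion)."""
    taxa = tuple(taxa)
    if len(set(taxa)) != len(taxa):
        raise ValueError("taxa must be distinct")
    if not taxa:
        raise ValueError("empty taxon set")
    if len(taxa) > MAX_TAXA:
        raise ValueError(
            f"refusing to enumerate {_n_topologies(len(taxa))} topologies for "
            f"n={len(taxa)} (limit n={MAX_TAXA})"
        )
    for nested in _nested_topologies(taxa):
        yield RootedTree.from_nested(nested)


def exact_gd(instance: ProblemInstance) -> tuple[int, list[RootedTree]]:
    """Minimum duplication cost over all species-tree topologies on the
    instance's taxon set, together with *all* optima (deduplicated by
    canonical Newick)."""
    best: int | None = None
    optima: list[RootedTree] = []
    seen: set[str] = set()
    for S in all_species_trees(instance.taxa):
        cost = total_dup_cost(instance, S)
        if best is None or cost < best:
            best = cost
            optima = [S]
            seen = {S.canonical_newick()}
        elif cost == best:
            key = S.canonical_newick()
            if key not in seen:
                seen.add(key)
                optima.append(S)
    assert best is not None
    return best, optima
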