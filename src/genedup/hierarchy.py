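"""Binary hierarchies: the cluster-set representation of binary trees.

A full binary tree on a taxon set F is equivalent to a *binary hierarchy*:
a family of subsets of F containing F and every singleton, pairwise
compatible (any two sets are nested or disjoint), of cardinality exactly
2|F| - 1.  The ILP encodes a candidate species tree as the n - 2
non-trivial columns of a 0/1 taxon-by-cluster matrix; this module validates
such families and converts them back into trees.

Pairwise compatibility of two 0/1 columns is the classic three-gamete
condition: the columns are incompatible iff rows with the patterns (0,1),
(1,0) and (1,1) all occur.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .tree_core import RootedTree


class HierarchyError(ValueError):
    """The given set family is not a binary hierarchy."""


def three_gamete_compatible(col_p: Sequence[int], col_q: Sequence[int]) -> bool:
    """True iff the two clusters encoded by the bit-vectors are nested or
    disjoint; false iff the gametes (0,1), (1,0) and (1,1) all occur."""
    if len(col_p) != len(col_q):
        raise ValueError(f"column length mismatch: {len(col_p)} vs {len(col_q)}")
    g01 = g10 = g11 = False
    for x, y in zip(col_p, col_q):
        if x and y:
            g11 = True
        elif x:
            g10 = True
        elif y:
            g01 = True
        if g01 and g10 and g11:
            return False
    return True


def _compatible_sets(a: frozenset, b: frozenset) -> bool:
    inter = a & b
    return not inter or inter == a or inter == b


def is_binary_hierarchy(sets: Iterable[Iterable[str]], F: Iterable[str]) -> bool:
    """Check the three defining properties: trivial sets present, pairwise
    compatibility, and cardinality 2|F| - 1."""
    fam = {frozenset(s) for s in sets}
    full = frozenset(F)
    if full not in fam:
        return False
    if any(frozenset((x,)) not in fam for x in full):
        return False
    if len(fam) != 2 * len(full) - 1:
        return False
    fam_l = sorted(fam, key=lambda s: (len(s), sorted(s)))
    for i in range(len(fam_l)):
        if not fam_l[i] <= full:
            return False
        for j in range(i + 1, len(fam_l)):
            if not _compatible_sets(fam_l[i], fam_l[j]):
                return False
    return True


def tree_from_clusters(sets: Iterable[Iterable[str]]) -> RootedTree:
    """Build the unique full binary tree whose cluster set is ``sets``.

    Inverse of :func:`genedup.tree_core.clusters`.  Clusters are sorted by
    decreasing size and each is attached under the smallest cluster that
    strictly contains it.
    """
    fam = {frozenset(s) for s in sets}
    if not fam:
        raise HierarchyError("empty cluster set")
    full = frozenset().union(*fam)
    if full not in fam:
        raise HierarchyError("trivial set property fails: full taxon set missing")
    missing = [x for x in sorted(full) if frozenset((x,)) not in fam]
    if missing:
        raise HierarchyError(f"trivial set property fails: singletons missing for {missing}")
    if len(fam) != 2 * len(full) - 1:
        raise HierarchyError(
            f"cardinality property fails: {len(fam)} clusters for {len(full)} taxa "
            f"(need {2 * len(full) - 1})"
        )

    ordered = sorted(fam, key=lambda s: (-len(s), sorted(s)))
    children_sets: dict[frozenset, list[frozenset]] = {c: [] for c in fam}
    # ordered[0] == full; attach every other cluster under its smallest
    # strict superset seen so far (sizes are non-increasing, so supersets
    # precede subsets)
    for c in ordered[1:]:
        parent = None
        for cand in ordered:
            if cand is c or len(cand) <= len(c):
                continue
            if c <= cand and (parent is None or len(cand) < len(parent)):
                parent = cand
        if parent is None:
            raise HierarchyError(f"compatibility fails: cluster {sorted(c)} has no parent")
        if not _compatible_sets(c, parent):  # pragma: no cover - subset by construction
            raise HierarchyError("incompatible clusters")
        children_sets[parent].append(c)

    for c, kids in children_sets.items():
        if len(c) == 1:
            if kids:
                raise HierarchyError(f"singleton {sorted(c)} has children")
        elif len(kids) != 2:
            raise HierarchyError(
                f"compatibility fails: cluster {sorted(c)} has {len(kids)} child "
                "clusters (binary hierarchy requires 2)"
            )
        else:
            a, b = kids
            if a & b or (a | b) != c:
                raise HierarchyError(
                    f"children {sorted(a)}, {sorted(b)} do not partition {sorted(c)}"
                )

    children: dict[int, tuple[int, int]] = {}
    labels: dict[int, str] = {}
    counter = iter(range(10**9))

    def build(c: frozenset) -> int:
        v = next(counter)
        if len(c) == 1:
            (labels[v],) = c
        else:
            a, b = children_sets[c]
            children[v] = (build(a), build(b))
        return v

    root = build(full)
    return RootedTree(children, labels, root)


@dataclass(frozen=True)
class ClusterMatrix:
    """The 0/1 taxon-by-cluster matrix of a candidate species tree.

    Rows follow ``taxa`` (lexicographic, fixed per problem instance);
    each column encodes one *non-trivial* cluster (size between 2 and
    n - 1).  The full set and the singletons are implicit.
    """

    taxa: tuple[str, ...]
    columns: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        n = len(self.taxa)
        if tuple(sorted(self.taxa)) != self.taxa:
            raise ValueError("taxa must be sorted")
        if len(self.columns) > max(0, n - 2):
            raise ValueError(f"at most n-2 = {n - 2} non-trivial columns allowed")
        seen = set()
        for col in self.columns:
            if len(col) != n:
                raise ValueError("column length != number of taxa")
            s = sum(col)
            if not (2 <= s <= n - 1):
                raise ValueError(f"column {col} is trivial (sum {s})")
            if col in seen:
                raise ValueError(f"duplicate column {col}")
            seen.add(col)
        for i, p in enumerate(self.columns):
            for q in self.columns[i + 1 :]:
                if not three_gamete_compatible(p, q):
                    raise ValueError(f"incompatible columns {p} and {q}")

    def cluster_sets(self) -> set[frozenset[str]]:
        """All clusters: stored columns plus the implicit trivial sets."""
        out = {frozenset(self.taxa)}
        out.update(frozenset((t,)) for t in self.taxa)
        for col in self.columns:
            out.add(frozenset(t for t, bit in zip(self.taxa, col) if bit))
        return out


def tree_from_matrix(M: ClusterMatrix) -> RootedTree:
    """Decode the species tree encoded by a feasible ILP assignment."""
    return tree_from_clusters(M.cluster_sets())
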