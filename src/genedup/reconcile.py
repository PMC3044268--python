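"""LCA reconciliation and the duplication / triple-inconsistency costs.

Given a gene tree G and a species tree S, the LCA mapping sends every gene
vertex to the least common ancestor in S of the species sampled below it.
An internal gene vertex is a *duplication* w.r.t. S when its image coincides
with the image of one of its children.  The total number of duplication
vertices, summed over a collection of gene trees, is the quantity the solver
minimizes over candidate species trees.

Duplication has an equivalent, purely combinatorial characterization: a gene
vertex is a duplication iff at least one rooted triple it roots (taken at the
species level) is *not* displayed by S.  That equivalence is what makes a
linear formulation possible, and this module provides both sides of it so the
equivalence can be asserted rather than assumed.

Non-injective leaf mappings (several gene copies per species) are handled by
preprocessing: a gene vertex whose two children's species sets overlap is a
duplication under *every* species tree, so such "forced" vertices are counted
as a constant and removed from the optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

from .tree_core import RootedTree, RootedTriple


class NotComparableError(ValueError):
    """A gene leaf refers to a species absent from the species tree."""


LeafMap = dict[str, str] | None  # gene leaf label -> species label; None = identity


def species_of(tree: RootedTree, v: int, leaf_to_species: LeafMap = None) -> str:
    """Species label of gene leaf ``v`` (identity when no map is given)."""
    lab = tree.label(v)
    if leaf_to_species is None:
        return lab
    return leaf_to_species.get(lab, lab)


def _species_below(tree: RootedTree, leaf_to_species: LeafMap) -> dict[int, frozenset[str]]:
    out: dict[int, frozenset[str]] = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            out[v] = frozenset((species_of(tree, v, leaf_to_species),))
        else:
            a, b = tree.children(v)
            out[v] = out[a] | out[b]
    return out


@dataclass(frozen=True)
class ProblemInstance:
    """A gene-duplication problem instance: a set of rooted binary gene trees
    plus an optional gene-leaf -> species-label mapping.

    When no mapping is supplied the gene leaf labels *are* the species
    labels.  The taxon set X is the union of species labels over all gene
    trees; gene trees need not each contain every taxon.
    """

    gene_trees: tuple[RootedTree, ...]
    leaf_to_species: dict[str, str] | None = None

    def __post_init__(self):
        if not self.gene_trees:
            raise ValueError("instance needs at least one gene tree")
        object.__setattr__(self, "gene_trees", tuple(self.gene_trees))

    def species(self, gi: int, v: int) -> str:
        return species_of(self.gene_trees[gi], v, self.leaf_to_species)

    @cached_property
    def taxa(self) -> tuple[str, ...]:
        """Sorted taxon set X."""
        labs: set[str] = set()
        for gi, g in enumerate(self.gene_trees):
            labs.update(self.species(gi, v) for v in g.leaves())
        return tuple(sorted(labs))

    @property
    def n(self) -> int:
        return len(self.taxa)

    @property
    def k(self) -> int:
        return len(self.gene_trees)

    @property
    def l(self) -> int:
        """Total vertex count over all gene trees."""
        return sum(len(g) for g in self.gene_trees)

    @cached_property
    def m(self) -> int:
        """Number of distinct species-level triples displayed across all
        gene trees."""
        trips: set[RootedTriple] = set()
        for gi, g in enumerate(self.gene_trees):
            below = _species_below(g, self.leaf_to_species)
            for u in g.internal_nodes():
                a, b = g.children(u)
                for side, other in ((below[a], below[b]), (below[b], below[a])):
                    sl = sorted(side)
                    for i in range(len(sl)):
                        for j in range(i + 1, len(sl)):
                            for z in other:
                                if z != sl[i] and z != sl[j]:
                                    trips.add(RootedTriple.of(sl[i], sl[j], z))
        return len(trips)


@dataclass
class TreeReconciliation:
    """Per-gene-tree reconciliation detail."""

    mapping: dict[int, int]  # gene vertex -> species-tree vertex
    duplication_vertices: frozenset[int]
    t_inconsistent_vertices: frozenset[int]
    forced_vertices: frozenset[int]

    @property
    def dup(self) -> int:
        return len(self.duplication_vertices)

    @property
    def tin(self) -> int:
        return len(self.t_inconsistent_vertices)


@dataclass
class ReconciliationReport:
    """Reconciliation of every gene tree of an instance against one species
    tree, with total duplication and triple-inconsistency costs.

    The per-vertex equality of the two costs (the duplication /
    t-inconsistency equivalence) is asserted at construction time.
    """

    species_tree: RootedTree
    per_tree: list[TreeReconciliation] = field(default_factory=list)

    @property
    def total_dup(self) -> int:
        return sum(t.dup for t in self.per_tree)

    @property
    def total_tin(self) -> int:
        return sum(t.tin for t in self.per_tree)

    def assert_equivalence(self) -> None:
        for i, t in enumerate(self.per_tree):
            if t.duplication_vertices != t.t_inconsistent_vertices:
                raise AssertionError(
                    f"gene tree {i}: duplication vertices "
                    f"{sorted(t.duplication_vertices)} != t-inconsistent "
                    f"vertices {sorted(t.t_inconsistent_vertices)}"
                )


class _SpeciesIndex:
    """Precomputed lookups on a species tree for repeated reconciliations."""

    __slots__ = ("tree", "leaf_of")

    def __init__(self, S: RootedTree):
        self.tree = S
        self.leaf_of: dict[str, int] = {}
        for v in S.leaves():
            lab = S.label(v)
            if lab in self.leaf_of:
                raise ValueError(f"species tree repeats label {lab!r}")
            self.leaf_of[lab] = v

    def require(self, label: str) -> int:
        try:
            return self.leaf_of[label]
        except KeyError:
            raise NotComparableError(
                f"gene tree not comparable to species tree: species {label!r} missing"
            ) from None

    def lca_labels(self, labels) -> int:
        return self.tree.lca_nodes(self.require(lab) for lab in labels)

    def displays(self, x: str, y: str, z: str) -> bool:
        """Does the species tree display the triple xy|z?"""
        t = self.tree
        l_xy = t.lca_nodes((self.require(x), self.require(y)))
        return l_xy != t.lca_nodes((l_xy, self.require(z)))


def lca_mapping(
    G: RootedTree, S: RootedTree, leaf_to_species: LeafMap = None
) -> dict[int, int]:
    """The LCA mapping M: each gene vertex to LCA_S of the species below it.

    Computed bottom-up in one postorder pass: a leaf maps to its species'
    leaf in S, an internal vertex to the LCA of its children's images.
    """
    idx = _SpeciesIndex(S)
    mapping: dict[int, int] = {}
    for v in G.postorder():
        if G.is_leaf(v):
            mapping[v] = idx.require(species_of(G, v, leaf_to_species))
        else:
            a, b = G.children(v)
            mapping[v] = S.lca_nodes((mapping[a], mapping[b]))
    return mapping


def duplication_vertices(
    G: RootedTree, S: RootedTree, leaf_to_species: LeafMap = None
) -> frozenset[int]:
    """Internal gene vertices whose LCA-mapping image equals a child's image."""
    mapping = lca_mapping(G, S, leaf_to_species)
    return frozenset(
        g
        for g in G.internal_nodes()
        if any(mapping[g] == mapping[c] for c in G.children(g))
    )


def forced_duplications(G: RootedTree, leaf_to_species: LeafMap = None) -> frozenset[int]:
    """Internal gene vertices whose two children's species sets overlap.

    Such a vertex is a duplication w.r.t. every species tree, so it can be
    settled by preprocessing and excluded from the optimization.  For an
    injective leaf mapping the result is always empty.
    """
    below = _species_below(G, leaf_to_species)
    out = set()
    for v in G.internal_nodes():
        a, b = G.children(v)
        if below[a] & below[b]:
            out.add(v)
    return frozenset(out)


def t_inconsistent_vertices(
    G: RootedTree, S: RootedTree, leaf_to_species: LeafMap = None
) -> frozenset[int]:
    """Internal gene vertices rooting at least one species-level triple not
    displayed by S, plus all forced vertices.

    Triples are taken at the species level: the ingroup pair comes from one
    child subtree's species set and the outgroup from the other's, all three
    pairwise distinct.  Forced vertices (overlapping child species sets) are
    flagged outright -- they are duplications for every S, and counting them
    here preserves the duplication/t-inconsistency equivalence for
    non-injective leaf mappings.
    """
    idx = _SpeciesIndex(S)
    below = _species_below(G, leaf_to_species)
    # comparability check mirrors lca_mapping's error contract
    for lab in below[G.root]:
        idx.require(lab)
    out: set[int] = set()
    for v in G.internal_nodes():
        a, b = G.children(v)
        A, B = below[a], below[b]
        if A & B:
            out.add(v)
            continue
        inconsistent = False
        for side, other in ((A, B), (B, A)):
            if inconsistent or len(side) < 2:
                continue
            sl = sorted(side)
            for i in range(len(sl)):
                for j in range(i + 1, len(sl)):
                    for z in other:
                        if not idx.displays(sl[i], sl[j], z):
                            inconsistent = True
                            break
                    if inconsistent:
                        break
                if inconsistent:
                    break
        if inconsistent:
            out.add(v)
    return frozenset(out)


def _report(
    instance: ProblemInstance, S: RootedTree, check_equivalence: bool
) -> ReconciliationReport:
    report = ReconciliationReport(species_tree=S)
    for g in instance.gene_trees:
        mapping = lca_mapping(g, S, instance.leaf_to_species)
        dups = frozenset(
            v
            for v in g.internal_nodes()
            if any(mapping[v] == mapping[c] for c in g.children(v))
        )
        tin = t_inconsistent_vertices(g, S, instance.leaf_to_species)
        forced = forced_duplications(g, instance.leaf_to_species)
        report.per_tree.append(
            TreeReconciliation(
                mapping=mapping,
                duplication_vertices=dups,
                t_inconsistent_vertices=tin,
                forced_vertices=forced,
            )
        )
    if check_equivalence:
        report.assert_equivalence()
    return report


def dup_cost(instance: ProblemInstance, S: RootedTree) -> ReconciliationReport:
    """Full reconciliation report of the instance against S; ``total_dup``
    is the duplication cost Dup(G, S) summed over the gene-tree set."""
    return _report(instance, S, check_equivalence=False)


def tin_cost(instance: ProblemInstance, S: RootedTree) -> ReconciliationReport:
    """As :func:`dup_cost`, but additionally asserts the per-vertex
    duplication / t-inconsistency equivalence before returning."""
    return _report(instance, S, check_equivalence=True)


def total_dup_cost(instance: ProblemInstance, S: RootedTree) -> int:
    """Duplication cost only, without building a report (hot path for the
    exhaustive oracle)."""
    idx = _SpeciesIndex(S)
    S_tree = S
    total = 0
    for g in instance.gene_trees:
        mapping: dict[int, int] = {}
        for v in g.postorder():
            if g.is_leaf(v):
                mapping[v] = idx.require(species_of(g, v, instance.leaf_to_species))
            else:
                a, b = g.children(v)
                ma, mb = mapping[a], mapping[b]
                mv = S_tree.lca_nodes((ma, mb))
                mapping[v] = mv
                if mv == ma or mv == mb:
                    total += 1
    return total


def representative_triples(
    G: RootedTree, leaf_to_species: LeafMap = None
) -> dict[int, list[RootedTriple]]:
    """An O(n)-sized set of species-level triples per internal gene vertex
    that stands in for *all* triples the vertex roots.

    For a vertex u with disjoint child species sets A and B, pick the
    lexicographically smallest representatives a = min(A), b = min(B) and
    return { ax|b : x in A\\{a} } + { bz|a : z in B\\{b} }.  All triples
    rooted at u are displayed by a species tree S iff all of these
    representatives are: the representatives pin every element of A strictly
    inside one child of LCA_S(a, b) and every element of B inside the other,
    which forces each xy|z with x, y in A and z in B (and symmetrically).

    Vertices whose child species sets overlap are forced duplications and
    have no triple representation (they are excluded from the result);
    vertices spanning fewer than three species get an empty list -- they can
    never be duplications.
    """
    below = _species_below(G, leaf_to_species)
    out: dict[int, list[RootedTriple]] = {}
    for u in G.internal_nodes():
        ca, cb = G.children(u)
        A, B = below[ca], below[cb]
        if A & B:
            continue  # forced vertex: no triple representation
        if len(A) + len(B) < 3:
            out[u] = []
            continue
        a = min(A)
        b = min(B)
        reps = [RootedTriple.of(a, x, b) for x in sorted(A) if x != a]
        reps += [RootedTriple.of(b, z, a) for z in sorted(B) if z != b]
        out[u] = reps
    return out
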