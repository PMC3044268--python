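"""Rooted full binary trees, Newick I/O, and basic topological queries.

Every object handled by this package -- gene trees and species trees alike --
is a *full* binary rooted tree: each vertex has exactly two or zero children.
Only the topology and the leaf labels are semantic; branch lengths, internal
node labels, and Newick comments are parsed and discarded.

Leaf labels within a species tree must be pairwise distinct.  Gene trees may
repeat labels (several gene copies sampled from one species), so operations
that require distinct labels (clusters, displayed triples) raise on repeats
and gene-tree code paths work with node sets instead.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Iterator

import dendropy


class NewickError(ValueError):
    """Malformed Newick input (message carries the source position)."""


class NonBinaryTreeError(ValueError):
    """An internal vertex has a number of children different from two."""


class TreeStructureError(ValueError):
    """An operation's structural precondition on the tree is violated."""


@dataclass(frozen=True, order=True)
class RootedTriple:
    """A rooted three-leaf tree ``xy|z``: the ingroup pair is closer to each
    other than either is to the outgroup ``z``.

    Stored in canonical form: ``ingroup`` is the lexicographically sorted
    pair, so equality and hashing ignore pair order.
    """

    ingroup: tuple[str, str]
    outgroup: str

    def __post_init__(self) -> None:
        x, y = self.ingroup
        if x == y or self.outgroup in (x, y):
            raise ValueError(f"triple labels must be distinct: {x}, {y}, {self.outgroup}")
        if x > y:
            object.__setattr__(self, "ingroup", (y, x))

    @staticmethod
    def of(x: str, y: str, z: str) -> "RootedTriple":
        return RootedTriple((x, y), z)

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.ingroup[0]}{self.ingroup[1]}|{self.outgroup}"


class RootedTree:
    """A rooted full binary tree with string-labeled leaves.

    Vertices are small integers.  The structure is immutable once built;
    all derived indices (depths, leaf sets) are computed eagerly because
    trees in this package are small (tens of vertices).
    """

    __slots__ = (
        "_children",
        "_parent",
        "_label",
        "root",
        "_depth",
        "_subtree_leaves",
        "_label_index",
        "_dup_label",
    )

    def __init__(self, children: dict[int, tuple[int, int]], labels: dict[int, str], root: int):
        self._children: dict[int, tuple[int, int]] = dict(children)
        self._label: dict[int, str] = dict(labels)
        self.root = root
        self._parent: dict[int, int] = {}
        for v, (a, b) in self._children.items():
            self._parent[a] = v
            self._parent[b] = v
        self._validate()
        self._depth: dict[int, int] = {}
        self._subtree_leaves: dict[int, tuple[int, ...]] = {}
        self._index()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def from_nested(nested) -> "RootedTree":
        """Build from nested pairs, e.g. ``(("a", "b"), "c")``."""
        children: dict[int, tuple[int, int]] = {}
        labels: dict[int, str] = {}
        counter = iter(range(10**9))

        def build(x) -> int:
            v = next(counter)
            if isinstance(x, tuple):
                if len(x) != 2:
                    raise NonBinaryTreeError(f"nested node has {len(x)} children")
                a = build(x[0])
                b = build(x[1])
                children[v] = (a, b)
            else:
                labels[v] = str(x)
            return v

        root = build(nested)
        return RootedTree(children, labels, root)

    def _validate(self) -> None:
        seen: set[int] = set()
        stack = [self.root]
        while stack:
            v = stack.pop()
            if v in seen:
                raise TreeStructureError(f"vertex {v} reachable twice (cycle or DAG)")
            seen.add(v)
            if v in self._children:
                stack.extend(self._children[v])
            elif v not in self._label or not self._label[v]:
                raise TreeStructureError(f"leaf {v} lacks a non-empty label")
        if len(seen) != len(self._children) + len(self._label):
            raise TreeStructureError("disconnected vertices present")
        if self.root in self._parent:
            raise TreeStructureError("root has a parent")

    def _index(self) -> None:
        order: list[int] = []
        stack = [(self.root, 0)]
        while stack:
            v, d = stack.pop()
            self._depth[v] = d
            order.append(v)
            for c in self._children.get(v, ()):
                stack.append((c, d + 1))
        for v in reversed(order):
            if v in self._children:
                a, b = self._children[v]
                self._subtree_leaves[v] = self._subtree_leaves[a] + self._subtree_leaves[b]
            else:
                self._subtree_leaves[v] = (v,)
        self._label_index: dict[str, int] = {}
        self._dup_label: str | None = None
        for v, lab in self._label.items():
            if lab in self._label_index and self._dup_label is None:
                self._dup_label = lab
            self._label_index[lab] = v

    # -- queries --------------------------------------------------------------

    def nodes(self) -> Iterator[int]:
        yield from self._depth

    def internal_nodes(self) -> Iterator[int]:
        yield from self._children

    def is_leaf(self, v: int) -> bool:
        return v not in self._children

    def children(self, v: int) -> tuple[int, int]:
        return self._children.get(v, ())

    def parent(self, v: int) -> int | None:
        return self._parent.get(v)

    def label(self, v: int) -> str:
        return self._label[v]

    def depth(self, v: int) -> int:
        return self._depth[v]

    def leaves(self, v: int | None = None) -> tuple[int, ...]:
        """Leaf vertices of the subtree rooted at ``v`` (default: whole tree)."""
        return self._subtree_leaves[self.root if v is None else v]

    def leaf_labels(self, v: int | None = None) -> list[str]:
        return [self._label[u] for u in self.leaves(v)]

    @property
    def n_leaves(self) -> int:
        return len(self._label)

    def __len__(self) -> int:
        return len(self._depth)

    def postorder(self) -> Iterator[int]:
        stack = [self.root]
        out: list[int] = []
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self._children.get(v, ()))
        return iter(reversed(out))

    def lca_nodes(self, vertices: Iterable[int]) -> int:
        """LCA of a non-empty set of vertices, by parent-pointer walks."""
        it = iter(vertices)
        try:
            a = next(it)
        except StopIteration:
            raise ValueError("LCA of an empty vertex set is undefined")
        for b in it:
            while self._depth[a] > self._depth[b]:
                a = self._parent[a]
            while self._depth[b] > self._depth[a]:
                b = self._parent[b]
            while a != b:
                a = self._parent[a]
                b = self._parent[b]
        return a

    def leaf_by_label(self) -> dict[int, str]:
        return dict(self._label)

    # -- canonical form -------------------------------------------------------

    def canonical_newick(self) -> str:
        return write_newick(self)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RootedTree):
            return NotImplemented
        return self.canonical_newick() == other.canonical_newick()

    def __hash__(self) -> int:
        return hash(self.canonical_newick())

    def __repr__(self) -> str:  # pragma: no cover
        return f"RootedTree({self.canonical_newick()!r})"


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str) -> RootedTree:
    """Parse a single rooted Newick string into a :class:`RootedTree`.

    Branch lengths, internal labels, quoted labels and ``[...]`` comments
    are accepted and discarded; only topology and leaf labels are kept.
    Duplicate leaf labels are permitted (gene trees may carry several
    copies per species).  Any internal vertex with more than two children
    is rejected; a trifurcation at the root is the classic signature of an
    unrooted tree, which must be rooted upstream of this package.
    """
    if not text.strip():
        raise NewickError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy error messages carry line/column
        raise NewickError(f"malformed Newick: {exc}") from exc

    children: dict[int, tuple[int, int]] = {}
    labels: dict[int, str] = {}
    counter = iter(range(10**9))

    def convert(node) -> int:
        v = next(counter)
        kids = node.child_nodes()
        if len(kids) == 0:
            if node.label is None or node.label == "":
                raise NewickError("leaf without a label")
            labels[v] = str(node.label)
        elif len(kids) == 1:
            # unary vertices carry no topological information; suppress them
            return convert(kids[0])
        elif len(kids) == 2:
            a = convert(kids[0])
            b = convert(kids[1])
            children[v] = (a, b)
        else:
            where = "the root" if node.parent_node is None else f"internal node {node.label or v}"
            hint = (
                "; a trifurcating root usually means the tree is unrooted -- "
                "root it before use" if node.parent_node is None else ""
            )
            raise NonBinaryTreeError(f"non-binary tree: {where} has {len(kids)} children{hint}")
        return v

    root = convert(dtree.seed_node)
    return RootedTree(children, labels, root)


def _quote_label(label: str) -> str:
    if any(c in label for c in "()[]{}:;,'\t\n ") or label == "":
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: RootedTree) -> str:
    """Serialize in canonical form: children of every vertex are emitted in
    order of their lexicographically smallest descendant leaf label, so two
    isomorphic trees always produce byte-identical output."""
    smallest: dict[int, str] = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            smallest[v] = tree.label(v)
        else:
            a, b = tree.children(v)
            smallest[v] = min(smallest[a], smallest[b])

    out = io.StringIO()

    def emit(v: int) -> None:
        if tree.is_leaf(v):
            out.write(_quote_label(tree.label(v)))
            return
        a, b = tree.children(v)
        if (smallest[a], a) > (smallest[b], b):
            a, b = b, a
        out.write("(")
        emit(a)
        out.write(",")
        emit(b)
        out.write(")")

    emit(tree.root)
    out.write(";")
    return out.getvalue()


def read_newick_file(path) -> list[RootedTree]:
    """Read a multi-tree Newick file: one tree per line, blank lines and
    ``#``-prefixed comment lines skipped."""
    trees: list[RootedTree] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                trees.append(parse_newick(line))
            except ValueError as exc:
                raise type(exc)(f"{path}:{lineno}: {exc}") from exc
    return trees


# ---------------------------------------------------------------------------
# Topological queries


def _require_distinct_labels(tree: RootedTree, op: str) -> dict[str, int]:
    if tree._dup_label is not None:
        raise TreeStructureError(
            f"{op} requires distinct leaf labels; {tree._dup_label!r} repeats"
        )
    return tree._label_index


def lca(tree: RootedTree, labels: Iterable[str]) -> int:
    """LCA vertex of a non-empty set of leaf labels (each must occur once)."""
    by_label = _require_distinct_labels(tree, "lca")
    vertices = []
    for lab in labels:
        if lab not in by_label:
            raise KeyError(f"label {lab!r} not in tree")
        vertices.append(by_label[lab])
    return tree.lca_nodes(vertices)


def clusters(tree: RootedTree) -> set[frozenset[str]]:
    """The cluster set H(T): for every vertex, the set of leaf labels below
    it.  A full binary tree on n leaves has exactly 2n-1 clusters."""
    _require_distinct_labels(tree, "clusters")
    return {frozenset(tree.leaf_labels(v)) for v in tree.nodes()}


def triples_at_vertex(tree: RootedTree, v: int) -> set[RootedTriple]:
    """Triples whose three leaves have LCA exactly ``v``: ingroup pair in one
    child subtree, outgroup in the other.  Empty for leaves."""
    if tree.is_leaf(v):
        return set()
    _require_distinct_labels(tree, "triples_at_vertex")
    a, b = tree.children(v)
    left = tree.leaf_labels(a)
    right = tree.leaf_labels(b)
    out: set[RootedTriple] = set()
    for side, other in ((left, right), (right, left)):
        if len(side) < 2:
            continue
        for i in range(len(side)):
            for j in range(i + 1, len(side)):
                for z in other:
                    out.add(RootedTriple.of(side[i], side[j], z))
    return out


def displayed_triples(tree: RootedTree) -> set[RootedTriple]:
    """Trip(T): every 3-subset of leaf labels resolved the way T displays it.
    |Trip(T)| = C(n, 3)."""
    _require_distinct_labels(tree, "displayed_triples")
    out: set[RootedTriple] = set()
    for v in tree.internal_nodes():
        out |= triples_at_vertex(tree, v)
    return out


def displays(tree: RootedTree, triple: RootedTriple) -> bool:
    """True iff ``tree`` displays ``triple`` (LCA of the ingroup pair lies
    strictly below the LCA of all three leaves)."""
    by_label = _require_distinct_labels(tree, "displays")
    x, y = triple.ingroup
    z = triple.outgroup
    for lab in (x, y, z):
        if lab not in by_label:
            raise KeyError(f"label {lab!r} not in tree")
    l_xy = tree.lca_nodes((by_label[x], by_label[y]))
    l_xyz = tree.lca_nodes((l_xy, by_label[z]))
    return l_xy != l_xyz
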