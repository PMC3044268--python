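# Methods

## Model

A *species tree* S is a rooted full binary tree with pairwise-distinct leaf
labels (taxa); a *gene tree* G is a rooted full binary tree whose leaves are
gene copies, each mapped to a taxon (by default the leaf label itself; a
two-column TSV can map several gene labels onto one species). The LCA
mapping M sends a gene leaf to its species' leaf in S and an internal gene
vertex to the LCA in S of its children's images. An internal gene vertex u
is a **duplication** w.r.t. S when M(u) equals the image of one of its
children; the duplication cost Dup(𝒢, S) sums duplication vertices over the
gene-tree collection, and the solver seeks min_S Dup(𝒢, S).

Two reformulations make the search space linear:

**Triple inconsistency.** u is a duplication iff some rooted triple xy|z
with {x,y} drawn from one child subtree and z from the other (at the species
level) is not displayed by S. The package computes both characterizations
independently — `duplication_vertices` by LCA mapping, `t_inconsistent_vertices`
by exhaustive triple membership — and the reconciliation report can assert
their vertex-wise equality on every input it sees, so the equivalence is a
checked invariant rather than an assumption.

**Cluster hierarchies.** Species trees on taxa X correspond one-to-one to
families of subsets of X containing X and all singletons, pairwise
compatible (nested or disjoint), with exactly 2|X|−1 members. The ILP
represents only the n−2 non-trivial clusters as columns of a binary matrix;
compatibility of two columns is the three-gamete condition (incompatible iff
row patterns (0,1), (1,0), (1,1) all occur).

## The integer program

Variables, all binary:

| family | count | meaning |
|---|---|---|
| M(i,p) | n(n−2) | taxon i belongs to non-trivial cluster p |
| C(p,q,xy) | 3·C(n−2,2) | column pair (p,q) exhibits gamete xy ∈ {01,10,11} |
| T(a,b,c,xyz) | 3 per needed triple | species triple {a,b,c} is displayed with topology xyz (011 = bc\|a, 101 = ac\|b, 110 = ab\|c) |
| D(g) | 1 per informative gene vertex | g is a duplication w.r.t. the matrix tree |

Constraints: column sums in [2, n−1]; strict descending order of the columns
read as n-bit binary numbers (n−3 constraints, coefficients 2^(n−1−i) —
the reason for the hard cap at 25 taxa); gamete detection lower bounds plus
C(p,q,01)+C(p,q,11)+C(p,q,10) = 2 per pair; triple detection lower bounds per
column plus a one-of-three equality per triple; and D(g) ≥ 1 − T(a,b,c,xyz)
for each representative triple of g. Objective: minimize Σ D(g).

**Representative triples.** A vertex u with disjoint child species sets A, B
roots |A|·|B|·(|A|+|B|−2)/2 triples, but consistency of all of them with any
S is equivalent to consistency of the (|A|−1)+(|B|−1) representatives
{a·x|b : x ∈ A∖{a}} ∪ {b·z|a : z ∈ B∖{b}} with a = min A, b = min B
(lexicographic, matching the canonical child order used everywhere): the
representatives pin all of A strictly inside one child of LCA_S(a,b) and all
of B inside the other, which forces every cross triple. This reduction is
what keeps the constraint count at O(kn²). Because the argument is subtle,
the test suite verifies the equivalence *exhaustively* over every species
tree on up to 6 taxa, and an `all_triples=True` build of the unreduced model
is kept for differential testing.

**Non-injective mappings.** A gene vertex whose children's species sets
overlap is a duplication under every species tree; such *forced* vertices
receive no D variable and contribute a constant offset added to the ILP
objective. Forced vertices are also flagged as triple-inconsistent by
definition, which preserves the Dup = Tin identity for multi-copy gene
trees (the triple characterization is otherwise silent about them). Gene
vertices spanning fewer than three species can never be duplications and get
no variable either; if *no* vertex is informative the solve short-circuits:
every species tree attains the forced offset.

**Solving.** The model is solver-agnostic (named binary variables, linear
constraints); the default backend is HiGHS branch-and-cut via
`scipy.optimize.milp`. Every returned assignment is independently
re-verified: integrality within 1e-6 then rounded, every constraint
re-evaluated in exact integer arithmetic, the M block decoded through the
hierarchy validator, and the decoded tree re-scored by LCA reconciliation —
`solve_gd` raises if the rescored cost differs from objective + offset.
Infeasibility on a fresh model is reported as a construction bug, since the
candidate-tree polytope is never empty for n ≥ 4. Optima are enumerated by
pinning the objective and adding no-good cuts over the M block; distinct
assignments can decode to one tree (the C variables are only lower-bounded),
so trees are deduplicated by canonical Newick form. Models can be exported
in CPLEX LP format with the stable variable names; a reader for exactly that
subset supports round-trip testing.

Instances with n ≤ 3 bypass the ILP (at most three topologies exist) and go
to the exhaustive solver, which enumerates all (2n−3)!! rooted binary
topologies by sequential taxon insertion and is the ground-truth oracle up
to n = 9.

## Simulator

`simulate_dataset` draws a species tree uniformly over rooted binary
topologies — sequential insertion of taxon i at one of 2i−3 uniformly chosen
attachment points, giving every topology probability 1/(2n−3)!! — then grows
each gene family by a depth-first walk over the species tree. Each visited
vertex experiences at most one event: duplication (probability `p_dup`,
default 0.25: the current subtree is replaced by two copies, and the walk
continues into both, so copies can duplicate again), loss (`p_loss`, default
0.3: the subtree is cut and the unary vertex suppressed), or nothing. The
defaults produce family sizes and duplication signal typical of moderate-copy
nuclear gene families. A loss that would erase the whole family triggers a
redraw of that family's walk (counted in the log); families with fewer than
three surviving leaves carry no triple signal and are regenerated (also
counted).

Every event is logged with a survival flag, giving an independent check on
the pipeline: with `p_loss = 0`, Dup(G, S_true) equals the number of logged
duplications exactly; with losses it is only an upper bound, because a
surviving duplication whose two copies retain disjoint species sets
reconciles as a speciation (e.g. S = (a,b), duplication at the root, then
loss of a in one copy and b in the other leaves a plain cherry). Both the
equality and the bound are asserted in the tests.

What the simulator does **not** emulate: branch lengths or rate
heterogeneity, sequence evolution and gene-tree estimation error, lateral
transfer, incomplete lineage sorting, or non-uniform species-tree priors.
Passing tests therefore demonstrate correctness of the *optimization* — the
ILP provably matches exhaustive search on the simulated conditions — not
robustness of gene tree parsimony to estimation artifacts in real data.

## Numerical and design choices

- **Determinism.** All randomness flows through a single seeded
  `random.Random`; child order in serialized trees is canonical
  (lexicographically smallest descendant leaf), making every output and
  iteration order reproducible. HiGHS is run single-threaded and is
  deterministic for a fixed model.
- **Canonical representatives.** The representative leaves a = min(A),
  b = min(B) are a free choice; lexicographic minima keep the model
  byte-stable across runs.
- **Tolerances.** Solver values are accepted as integral within 1e-6 and
  rounded; all downstream checks are exact integer arithmetic.
- **Scale.** The ILP is built for 4 ≤ n ≤ 25 taxa (the uniqueness-order
  coefficients 2^(n−1) are the binding numerical concern); the exhaustive
  oracle is capped at n = 9. Validation runs use n ≤ 6 against the oracle —
  945 topologies per instance keeps full enumeration honest and quick — and
  a 10-taxon, 100-family instance for the larger end-to-end check, which
  HiGHS solves to proven optimality in seconds.
- **Degenerate inputs.** Single-leaf gene trees are legal and contribute
  nothing; gene trees need not contain all taxa; unrooted (trifurcating-root)
  Newick input is rejected with a pointer to pre-root it rather than guessed
  at.

## Known limitations

- The duplication cost alone is optimized; losses, deep coalescence, and
  transfers are out of scope.
- Exactness comes from MILP: worst-case time is exponential, and practical
  limits sit in the low tens of taxa (gene-tree *count* scales benignly —
  constraints grow linearly in k and duplicate triples collapse onto shared
  T variables).
- Gene trees are taken as given and rooted; uncertainty in gene-tree
  estimation is not propagated.
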