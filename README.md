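# genedup

Exact species-tree inference by gene-duplication minimization (gene tree
parsimony), solved to proven optimality with integer linear programming.

## The problem

Gene families evolve by duplication and loss, so the tree of a gene family
(the *gene tree* G) routinely disagrees with the phylogeny of the species the
genes were sampled from (the *species tree* S). Reconciling G with a candidate
S via the LCA mapping — each gene vertex u maps to
M(u) = LCA_S of the species below u — identifies the gene vertices that must
be duplications: those with M(u) = M(v) for a child v. The **gene duplication
problem** asks, given a collection 𝒢 of rooted binary gene trees, for the
species tree S\* minimizing the total duplication count

```
Dup(𝒢) = min_S Σ_{G ∈ 𝒢} |{u ∈ V(G) : u is a duplication w.r.t. S}|
```

The problem is NP-hard, and heuristic hill-climbers carry no optimality
guarantee. `genedup` solves it *exactly* for moderate taxon counts by
exploiting two equivalences:

1. **Duplication ⇔ triple inconsistency.** A gene vertex is a duplication
   w.r.t. S iff it roots at least one rooted triple xy|z not displayed by S.
   This turns a recursive mapping condition into per-triple membership tests.
2. **Binary tree ⇔ binary hierarchy.** A species tree on n taxa is exactly a
   family of 2n−1 pairwise-compatible clusters, so candidate trees are the 0/1
   assignments of an n×(n−2) taxon-by-cluster matrix M constrained by the
   three-gamete compatibility test.

The resulting binary program has variables M(i,p) (matrix cells), C(p,q,xy)
(gamete indicators), T(a,b,c,xyz) (which topology of each species triple the
matrix displays), and D(g) (one per informative gene vertex), with objective
min Σ D(g) under constraints D(g) ≥ 1 − T(a,b,c,xyz) over an O(n)-sized set
of *representative* triples per vertex. Gene vertices whose two child subtrees
share a species (possible when a species contributed several gene copies) are
duplications under every S and are counted as a constant offset instead.
Solutions are decoded back into a tree and independently re-scored; the solver
is never trusted blindly.

## Worked example

Three gene families over species {a, b, c, d}; the third carries two copies
from species `a`, forcing one duplication regardless of the species tree:

```
$ cat genes.nwk
((a,b),c);
((a,c),b);
(((a,b),(c,a)),d);

$ genedup solve genes.nwk --oracle
{
  "cost": 2,
  "offset": 1,
  "species_tree": "(((a,c),b),d);",
  "per_tree_dup": [1, 0, 1],
  "oracle_cost": 2,
  ...
}
```

Reading the output: the optimal species tree `(((a,c),b),d);` implies 2
duplications in total — the forced multi-copy vertex in the third family
(`offset: 1`) plus one root duplication in the first family, whose triple
ab|c conflicts with the ac|b of the optimum. `--oracle` re-solves the
instance by exhaustive enumeration over all 15 four-taxon topologies and
confirms the ILP optimum (exit code 4 would signal a mismatch).

Other commands:

```
genedup score genes.nwk species.nwk      # Dup and Tin costs of a fixed tree
genedup simulate -n 10 -k 100 --seed 1 --out-prefix sim   # duplication/loss simulator
genedup solve genes.nwk --enumerate 10   # list all optimal species trees
genedup solve genes.nwk --lp-out m.lp    # export the CPLEX-LP model
```

The same functionality is available as a library:

```python
import genedup as gd
inst = gd.ProblemInstance(tuple(gd.read_newick_file("genes.nwk")))
cost, tree, report = gd.solve_gd(inst)
```

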