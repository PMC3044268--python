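"""The integer linear program for exact gene-duplication species-tree search.

The candidate species tree is encoded as the n-2 non-trivial columns of a
binary taxon-by-cluster matrix M; constraints force the columns (plus the
implicit trivial sets) to form a binary hierarchy, i.e. exactly one full
binary tree:

* non-triviality       -- every column sum lies in [2, n-1];
* uniqueness           -- columns strictly decrease under a binary-number
                          interpretation, so no column repeats;
* three-gamete test    -- indicator variables C(p,q,xy) detect the gametes
                          (0,1), (1,0), (1,1) of every column pair, and
                          C(p,q,01) + C(p,q,11) + C(p,q,10) = 2 rules out
                          incompatible pairs.

Rooted-triple indicators T(a,b,c,xyz) read the displayed topology of each
needed species triple off the matrix (topology codes 011, 101, 110 mean
bc|a, ac|b, ab|c).  A gene vertex g is triple-inconsistent -- equivalently,
a duplication -- exactly when one of the triples it roots is not displayed,
enforced through D(g) >= 1 - T(a,b,c,xyz) over an O(n)-sized set of
representative triples per vertex.  The objective minimizes the number of
flagged vertices; gene vertices that are duplications under every species
tree (overlapping child species sets) are counted in a constant offset
instead.
"""

from __future__ import annotations

import re
import time
from dataclasses import dataclass, field

from . import brute_force, hierarchy, reconcile
from .backends import BackendResult, Constraint, MILPBackend, default_backend
from .reconcile import ProblemInstance, ReconciliationReport
from .tree_core import RootedTree, RootedTriple

MAX_TAXA = 25  # uniqueness weights reach 2^(n-1); larger n risks solver numerics

TOPOLOGIES = ("011", "101", "110")


def triple_topology(triple: RootedTriple) -> tuple[tuple[str, str, str], str]:
    """Canonical (sorted) leaf set of a triple and its topology code:
    with {a,b,c} sorted, 011 = bc|a, 101 = ac|b, 110 = ab|c."""
    labels = tuple(sorted((*triple.ingroup, triple.outgroup)))
    code = {labels[0]: "011", labels[1]: "101", labels[2]: "110"}[triple.outgroup]
    return labels, code


def _sanitize(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9]", "_", label)


@dataclass
class ILPModel:
    """A solver-agnostic binary program with stable variable names.

    Variable families: ``M_{i}_{p}`` (taxon row i, column p), ``C_{p}_{q}_{xy}``
    (gamete indicators), ``T_{a}_{b}_{c}_{xyz}`` (triple indicators, species
    labels sanitized), ``D_{g}_{v}`` (per-gene-vertex duplication flags).
    """

    taxa: tuple[str, ...]
    n_columns: int
    variables: list[str] = field(default_factory=list)
    constraints: list[Constraint] = field(default_factory=list)
    objective: dict[str, float] = field(default_factory=dict)
    offset: int = 0  # forced duplications, added to the objective after solving
    # bookkeeping for decoding and diagnostics
    triple_vars: dict[tuple[str, str, str], dict[str, str]] = field(default_factory=dict)
    dup_vars: dict[str, tuple[int, int]] = field(default_factory=dict)  # var -> (tree, vertex)
    all_triples: bool = False

    def mvar(self, i: int, p: int) -> str:
        return f"M_{i}_{p}"

    def validate(self) -> None:
        declared = set(self.variables)
        if len(declared) != len(self.variables):
            raise ValueError("duplicate variable names")
        for con in self.constraints:
            undeclared = set(con.coeffs) - declared
            if undeclared:
                raise ValueError(f"constraint {con.name} uses undeclared {sorted(undeclared)}")
        if set(self.objective) - declared:
            raise ValueError("objective uses undeclared variables")


@dataclass
class Solution:
    """A verified solve outcome.  For status ``optimal`` every variable is
    0/1 and every constraint holds -- re-checked arithmetically, not taken
    from the solver."""

    status: str  # "optimal" | "infeasible" | "aborted"
    objective: int | None
    assignment: dict[str, int] | None
    backend: str
    wall_time: float
    detail: str = ""


class SolverError(RuntimeError):
    pass


def _vertex_triples_all(G, below, u) -> list[RootedTriple]:
    """Every species-level triple rooted at u (unreduced model)."""
    a, b = G.children(u)
    out: list[RootedTriple] = []
    for side, other in ((below[a], below[b]), (below[b], below[a])):
        sl = sorted(side)
        for i in range(len(sl)):
            for j in range(i + 1, len(sl)):
                for z in sorted(other):
                    out.append(RootedTriple.of(sl[i], sl[j], z))
    return out


def build_ilp(instance: ProblemInstance, all_triples: bool = False) -> ILPModel:
    """Assemble the full program for an instance with n >= 4 taxa.

    ``all_triples=True`` builds the unreduced model (one constraint per
    displayed triple per vertex instead of the O(n) representatives) for
    differential testing; both models have the same optimum.
    """
    taxa = instance.taxa
    n = len(taxa)
    if n < 4:
        raise ValueError(f"n={n} < 4: use the brute-force solver for tiny instances")
    if n > MAX_TAXA:
        raise ValueError(
            f"n={n} exceeds the supported maximum of {MAX_TAXA} taxa "
            "(uniqueness-constraint coefficients grow as 2^n)"
        )

    model = ILPModel(taxa=taxa, n_columns=n - 2, all_triples=all_triples)
    row = {t: i for i, t in enumerate(taxa)}

    # --- candidate-tree block -------------------------------------------
    for p in range(model.n_columns):
        for i in range(n):
            model.variables.append(model.mvar(i, p))

    for p in range(model.n_columns):
        col = {model.mvar(i, p): 1.0 for i in range(n)}
        model.constraints.append(Constraint(f"nontrivial_lo_{p}", dict(col), ">=", 2))
        model.constraints.append(Constraint(f"nontrivial_hi_{p}", dict(col), "<=", n - 1))

    # strict descending order of the columns read as n-bit binary numbers
    weights = [2 ** (n - 1 - i) for i in range(n)]
    for p in range(model.n_columns - 1):
        coeffs: dict[str, float] = {}
        for i in range(n):
            coeffs[model.mvar(i, p)] = float(weights[i])
            coeffs[model.mvar(i, p + 1)] = -float(weights[i])
        model.constraints.append(Constraint(f"unique_{p}_{p + 1}", coeffs, ">=", 1))

    for p in range(model.n_columns):
        for q in range(p + 1, model.n_columns):
            cvars = {xy: f"C_{p}_{q}_{xy}" for xy in ("01", "10", "11")}
            model.variables.extend(cvars.values())
            for i in range(n):
                mp, mq = model.mvar(i, p), model.mvar(i, q)
                model.constraints.append(
                    Constraint(f"gam01_{p}_{q}_{i}", {cvars["01"]: 1.0, mp: 1.0, mq: -1.0}, ">=", 0)
                )
                model.constraints.append(
                    Constraint(f"gam10_{p}_{q}_{i}", {cvars["10"]: 1.0, mp: -1.0, mq: 1.0}, ">=", 0)
                )
                model.constraints.append(
                    Constraint(f"gam11_{p}_{q}_{i}", {cvars["11"]: 1.0, mp: -1.0, mq: -1.0}, ">=", -1)
                )
            model.constraints.append(
                Constraint(
                    f"compat_{p}_{q}",
                    {cvars["01"]: 1.0, cvars["11"]: 1.0, cvars["10"]: 1.0},
                    "==",
                    2,
                )
            )

    # --- gene-tree block -------------------------------------------------
    vertex_triples: list[tuple[int, int, list[RootedTriple]]] = []
    offset = 0
    for gi, G in enumerate(instance.gene_trees):
        offset += len(reconcile.forced_duplications(G, instance.leaf_to_species))
        if all_triples:
            below = reconcile._species_below(G, instance.leaf_to_species)
            reps = {
                u: _vertex_triples_all(G, below, u)
                for u in G.internal_nodes()
                if not (below[G.children(u)[0]] & below[G.children(u)[1]])
            }
        else:
            reps = reconcile.representative_triples(G, instance.leaf_to_species)
        for u, triples in reps.items():
            if triples:
                vertex_triples.append((gi, u, triples))
    model.offset = offset

    needed: dict[tuple[str, str, str], None] = {}
    for _, _, triples in vertex_triples:
        for t in triples:
            labels, _ = triple_topology(t)
            needed.setdefault(labels, None)

    for labels in needed:
        a, b, c = labels
        sa, sb, sc = (_sanitize(x) for x in labels)
        tvars = {code: f"T_{sa}_{sb}_{sc}_{code}" for code in TOPOLOGIES}
        model.triple_vars[labels] = tvars
        model.variables.extend(tvars.values())
        ra, rb, rc = row[a], row[b], row[c]
        signs = {"011": (-1.0, 1.0, 1.0), "101": (1.0, -1.0, 1.0), "110": (1.0, 1.0, -1.0)}
        for code in TOPOLOGIES:
            wa, wb, wc = signs[code]
            for p in range(model.n_columns):
                coeffs = {
                    tvars[code]: 1.0,
                    model.mvar(ra, p): -wa,
                    model.mvar(rb, p): -wb,
                    model.mvar(rc, p): -wc,
                }
                model.constraints.append(
                    Constraint(f"trip_{sa}_{sb}_{sc}_{code}_{p}", coeffs, ">=", -1)
                )
        model.constraints.append(
            Constraint(
                f"trip_one_{sa}_{sb}_{sc}",
                {tvars[code]: 1.0 for code in TOPOLOGIES},
                "==",
                1,
            )
        )

    for gi, u, triples in vertex_triples:
        dvar = f"D_{gi}_{u}"
        model.variables.append(dvar)
        model.dup_vars[dvar] = (gi, u)
        model.objective[dvar] = 1.0
        for t in triples:
            labels, code = triple_topology(t)
            tvar = model.triple_vars[labels][code]
            model.constraints.append(
                Constraint(f"tin_{dvar}_{_sanitize(str(t))}", {dvar: 1.0, tvar: 1.0}, ">=", 1)
            )

    if not model.dup_vars:
        raise ValueError(
            "no gene vertex can vary with the species tree (empty objective); "
            "the optimum is the forced-duplication count -- use solve_gd"
        )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Solving and verification


def _verify_assignment(
    model: ILPModel,
    raw: dict[str, float],
    extra: list[Constraint] = (),
    tol: float = 1e-6,
) -> dict[str, int]:
    """Round a solver assignment to 0/1 and re-check every constraint
    arithmetically; raises SolverError on any violation."""
    assignment: dict[str, int] = {}
    for v in model.variables:
        x = raw[v]
        r = round(x)
        if abs(x - r) > tol or r not in (0, 1):
            raise SolverError(f"variable {v} = {x} is not integral/binary")
        assignment[v] = int(r)
    for con in list(model.constraints) + list(extra):
        lhs = sum(coef * assignment[v] for v, coef in con.coeffs.items())
        ok = (
            lhs <= con.rhs + tol
            if con.sense == "<="
            else lhs >= con.rhs - tol if con.sense == ">=" else abs(lhs - con.rhs) <= tol
        )
        if not ok:
            raise SolverError(f"constraint {con.name} violated: {lhs} {con.sense} {con.rhs}")
    return assignment


def solve(
    model: ILPModel,
    backend: MILPBackend | None = None,
    extra_constraints: list[Constraint] | None = None,
) -> Solution:
    """Minimize the model with the given backend and independently verify
    the returned assignment before trusting it."""
    backend = backend or default_backend()
    extra = list(extra_constraints or [])
    t0 = time.perf_counter()
    res: BackendResult = backend.solve(
        model.variables, model.objective, list(model.constraints) + extra
    )
    dt = time.perf_counter() - t0
    if res.status == "infeasible":
        if not extra:
            raise SolverError(
                "model infeasible -- the candidate-tree polytope is never empty, "
                "so this indicates a model-construction bug"
            )
        return Solution("infeasible", None, None, backend.name, dt, res.detail)
    if res.status != "optimal" or res.assignment is None:
        return Solution("aborted", None, None, backend.name, dt, res.detail)
    assignment = _verify_assignment(model, res.assignment, extra)
    obj = round(sum(model.objective.get(v, 0.0) * x for v, x in assignment.items()))
    return Solution("optimal", int(obj), assignment, backend.name, dt, res.detail)


def decode_matrix(model: ILPModel, assignment: dict[str, int]) -> hierarchy.ClusterMatrix:
    cols = []
    for p in range(model.n_columns):
        cols.append(tuple(assignment[model.mvar(i, p)] for i in range(len(model.taxa))))
    return hierarchy.ClusterMatrix(taxa=model.taxa, columns=tuple(cols))


def decode_tree(model: ILPModel, assignment: dict[str, int]) -> RootedTree:
    """The species tree encoded by a feasible assignment's M block."""
    return hierarchy.tree_from_matrix(decode_matrix(model, assignment))


def _ladder(taxa: tuple[str, ...]) -> RootedTree:
    nested = taxa[0]
    for t in taxa[1:]:
        nested = (nested, t)
    return RootedTree.from_nested(nested)


def solve_gd(
    instance: ProblemInstance,
    backend: MILPBackend | None = None,
    all_triples: bool = False,
) -> tuple[int, RootedTree, ReconciliationReport]:
    """End-to-end exact solve: optimal duplication cost, one optimal species
    tree, and the reconciliation report of the instance against it.

    Instances with n <= 3 taxa are dispatched to the exhaustive solver (at
    most three topologies exist); likewise when every informative gene
    vertex is forced, in which case every species tree is optimal.  The
    returned report is an end-to-end self-check: its recomputed total must
    equal the ILP objective plus the forced-duplication offset.
    """
    n = instance.n
    if n <= 3:
        cost, optima = brute_force.exact_gd(instance)
        tree = optima[0]
    else:
        try:
            model = build_ilp(instance, all_triples=all_triples)
        except ValueError as exc:
            if "empty objective" not in str(exc):
                raise
            # every species tree attains the forced-duplication floor
            offset = sum(
                len(reconcile.forced_duplications(G, instance.leaf_to_species))
                for G in instance.gene_trees
            )
            tree = _ladder(instance.taxa)
            report = reconcile.dup_cost(instance, tree)
            if report.total_dup != offset:  # pragma: no cover - invariant
                raise SolverError("forced-duplication accounting mismatch") from None
            return offset, tree, report
        sol = solve(model, backend)
        if sol.status != "optimal":
            raise SolverError(f"solver did not reach optimality: {sol.status} ({sol.detail})")
        tree = decode_tree(model, sol.assignment)
        cost = sol.objective + model.offset
    report = reconcile.dup_cost(instance, tree)
    if report.total_dup != cost:
        raise SolverError(
            f"self-check failed: ILP cost {cost} != rescored duplication "
            f"count {report.total_dup}"
        )
    return cost, tree, report


def enumerate_optima(
    model: ILPModel,
    backend: MILPBackend | None = None,
    limit: int = 100,
) -> list[RootedTree]:
    """All distinct optimal species trees, up to ``limit``.

    Repeatedly re-solves with the objective pinned to the optimum and a
    no-good cut excluding each previously seen M assignment.  Several ILP
    assignments can decode to the same tree (the gamete indicators are only
    lower-bounded), so trees are deduplicated by canonical form; cutting on
    the M block alone keeps the number of re-solves equal to the number of
    distinct trees.
    """
    if limit < 1:
        raise ValueError("limit must be positive")
    backend = backend or default_backend()
    first = solve(model, backend)
    if first.status != "optimal":
        raise SolverError(f"initial solve failed: {first.status}")
    z_star = first.objective
    pin = Constraint("pin_objective", dict(model.objective), "==", float(z_star))

    trees: list[RootedTree] = []
    seen: set[str] = set()
    cuts: list[Constraint] = [pin]
    sol = first
    while len(trees) < limit:
        tree = decode_tree(model, sol.assignment)
        key = tree.canonical_newick()
        if key not in seen:
            seen.add(key)
            trees.append(tree)
        coeffs: dict[str, float] = {}
        ones = 0
        for i in range(len(model.taxa)):
            for p in range(model.n_columns):
                v = model.mvar(i, p)
                if sol.assignment[v] == 1:
                    coeffs[v] = -1.0
                    ones += 1
                else:
                    coeffs[v] = 1.0
        cuts.append(Constraint(f"nogood_{len(cuts)}", coeffs, ">=", float(1 - ones)))
        sol = solve(model, backend, extra_constraints=cuts)
        if sol.status != "optimal":
            break
    return trees


# ---------------------------------------------------------------------------
# LP-format I/O (CPLEX LP dialect)


def write_lp(model: ILPModel, destination) -> None:
    """Write the model in CPLEX LP format with the stable variable names.

    ``destination`` is a path or a writable text file object.
    """
    close = False
    if isinstance(destination, (str, bytes)) or hasattr(destination, "__fspath__"):
        fh = open(destination, "w")
        close = True
    else:
        fh = destination
    try:
        fh.write("\\ gene-duplication ILP\n")
        fh.write("Minimize\n obj: ")
        fh.write(" + ".join(f"{v}" for v in model.objective))
        fh.write("\nSubject To\n")
        for con in model.constraints:
            terms = []
            for v, coef in con.coeffs.items():
                coef = int(coef) if float(coef).is_integer() else coef
                if coef >= 0:
                    terms.append(f"+ {coef} {v}")
                else:
                    terms.append(f"- {abs(coef)} {v}")
            sense = {"<=": "<=", ">=": ">=", "==": "="}[con.sense]
            rhs = int(con.rhs) if float(con.rhs).is_integer() else con.rhs
            fh.write(f" {con.name}: {' '.join(terms)} {sense} {rhs}\n")
        fh.write("Binary\n")
        for v in model.variables:
            fh.write(f" {v}\n")
        fh.write("End\n")
    finally:
        if close:
            fh.close()


def read_lp(source) -> ILPModel:
    """Read back an LP file written by :func:`write_lp` (that subset of the
    dialect only).  Used to confirm the emitted file is faithful; the
    result carries no decoding metadata."""
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        fh = open(source)
        close = True
    else:
        fh = source
    try:
        text = fh.read()
    finally:
        if close:
            fh.close()

    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("\\")]
    model = ILPModel(taxa=(), n_columns=0)
    section = None
    for ln in lines:
        stripped = ln.strip()
        low = stripped.lower()
        if low in ("minimize", "subject to", "binary", "end"):
            section = low
            continue
        if section == "minimize":
            body = stripped.split(":", 1)[1] if ":" in stripped else stripped
            for v in body.replace("+", " ").split():
                model.objective[v] = 1.0
        elif section == "subject to":
            name, body = stripped.split(":", 1)
            mm = re.match(r"(.*?)(<=|>=|=)\s*(-?\d+(?:\.\d+)?)\s*$", body.strip())
            if not mm:
                raise ValueError(f"cannot parse constraint line: {ln!r}")
            expr, sense, rhs = mm.groups()
            sense = "==" if sense == "=" else sense
            coeffs: dict[str, float] = {}
            for sign, num, var in re.findall(r"([+-])\s*(\d+(?:\.\d+)?)\s+(\S+)", expr):
                coeffs[var] = coeffs.get(var, 0.0) + (1 if sign == "+" else -1) * float(num)
            model.constraints.append(Constraint(name.strip(), coeffs, sense, float(rhs)))
        elif section == "binary":
            model.variables.extend(stripped.split())
    model.validate()
    return model
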