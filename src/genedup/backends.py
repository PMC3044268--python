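"""MILP solver backends.

The model builder is solver-agnostic: a backend receives named binary
variables, linear constraints and a linear objective, and returns a status
plus an assignment.  The default backend wraps :func:`scipy.optimize.milp`
(HiGHS branch-and-cut).  Any solver satisfying the small protocol below can
be substituted; solutions are independently re-verified downstream, so a
backend is never trusted blindly.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp


@dataclass(frozen=True)
class Constraint:
    """A linear constraint  sum(coeffs[v] * v)  <sense>  rhs."""

    name: str
    coeffs: dict[str, float]
    sense: str  # "<=", ">=", "=="
    rhs: float

    def __post_init__(self):
        if self.sense not in ("<=", ">=", "=="):
            raise ValueError(f"bad sense {self.sense!r}")


@dataclass
class BackendResult:
    status: str  # "optimal" | "infeasible" | "aborted"
    assignment: dict[str, float] | None
    wall_time: float
    detail: str = ""


class MILPBackend(Protocol):  # pragma: no cover - interface only
    name: str

    def solve(
        self,
        variables: Sequence[str],
        objective: dict[str, float],
        constraints: Sequence[Constraint],
    ) -> BackendResult: ...


class ScipyHighsBackend:
    """Binary MILP via scipy's HiGHS interface.

    Deterministic for a fixed model (HiGHS is single-threaded here and
    takes no random seed), which keeps end-to-end runs reproducible.
    """

    name = "scipy-highs"

    def __init__(self, time_limit: float | None = None):
        self.time_limit = time_limit

    def solve(self, variables, objective, constraints) -> BackendResult:
        idx = {v: i for i, v in enumerate(variables)}
        nv = len(variables)
        c = np.zeros(nv)
        for v, coef in objective.items():
            c[idx[v]] = coef

        rows, cols, vals = [], [], []
        lb = np.empty(len(constraints))
        ub = np.empty(len(constraints))
        for r, con in enumerate(constraints):
            for v, coef in con.coeffs.items():
                rows.append(r)
                cols.append(idx[v])
                vals.append(coef)
            if con.sense == "<=":
                lb[r], ub[r] = -np.inf, con.rhs
            elif con.sense == ">=":
                lb[r], ub[r] = con.rhs, np.inf
            else:
                lb[r] = ub[r] = con.rhs
        A = sparse.csr_matrix((vals, (rows, cols)), shape=(len(constraints), nv))

        options = {}
        if self.time_limit is not None:
            options["time_limit"] = self.time_limit
        t0 = time.perf_counter()
        res = milp(
            c,
            constraints=[LinearConstraint(A, lb, ub)] if len(constraints) else [],
            integrality=np.ones(nv),
            bounds=Bounds(0.0, 1.0),
            options=options,
        )
        dt = time.perf_counter() - t0
        if res.status == 0:
            assignment = {v: float(res.x[idx[v]]) for v in variables}
            return BackendResult("optimal", assignment, dt, res.message)
        if res.status == 2:
            return BackendResult("infeasible", None, dt, res.message)
        return BackendResult("aborted", None, dt, res.message)


def default_backend() -> ScipyHighsBackend:
    return ScipyHighsBackend()
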