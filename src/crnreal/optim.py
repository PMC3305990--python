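"""Solver-agnostic LP/MILP contract.

All realization algorithms talk to this thin layer instead of a concrete
solver.  The layer currently drives HiGHS through
:func:`scipy.optimize.linprog` / :func:`scipy.optimize.milp` with a fixed,
deterministic configuration (presolve on, default single-threaded simplex /
branch-and-bound), so identical programs yield identical results.  Solver
failures surface as an explicit ``error`` status, never as a silent wrong
answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.optimize as sopt

__all__ = ["LinearProgram", "SolveResult", "solve", "check_feasibility"]

Status = Literal["optimal", "infeasible", "unbounded", "error"]

#: constraint-violation slack accepted when re-checking solver output
FEASIBILITY_TOL = 1e-8


@dataclass
class LinearProgram:
    """A linear (or mixed-integer linear) program in standard data form.

    ``c`` and ``sense`` define the objective; ``a_eq x = b_eq`` the equality
    block; the optional ``a_ub x <= b_ub`` block carries inequality rows
    (used only by the cardinality MILP's linking constraints); ``bounds`` is
    an ``(n, 2)`` array of per-variable lower/upper bounds; ``integrality``
    flags binary/integer variables as in :func:`scipy.optimize.milp`.
    """

    c: np.ndarray
    bounds: np.ndarray
    a_eq: np.ndarray | None = None
    b_eq: np.ndarray | None = None
    a_ub: np.ndarray | None = None
    b_ub: np.ndarray | None = None
    integrality: np.ndarray | None = None
    sense: Literal["min", "max"] = "min"

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        self.bounds = np.asarray(self.bounds, dtype=float)
        n = self.c.size
        if self.bounds.shape != (n, 2):
            raise ValueError("bounds must be an (n, 2) array")
        if (self.bounds[:, 0] > self.bounds[:, 1] + 1e-15).any():
            raise ValueError("lower bounds exceed upper bounds")
        for a, b, name in ((self.a_eq, self.b_eq, "eq"), (self.a_ub, self.b_ub, "ub")):
            if (a is None) != (b is None):
                raise ValueError(f"a_{name} and b_{name} must be given together")
            if a is not None and np.asarray(a).shape != (np.asarray(b).size, n):
                raise ValueError(f"inconsistent {name}-constraint dimensions")

    @property
    def is_mip(self) -> bool:
        return self.integrality is not None and np.any(self.integrality)


@dataclass
class SolveResult:
    status: Status
    values: np.ndarray | None = None
    objective_value: float | None = None
    message: str = ""

    def __post_init__(self) -> None:
        if (self.status == "optimal") != (self.values is not None):
            raise ValueError("values must be present exactly when optimal")


_LINPROG_STATUS: dict[int, Status] = {0: "optimal", 2: "infeasible", 3: "unbounded"}
_MILP_STATUS: dict[int, Status] = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def solve(p: LinearProgram) -> SolveResult:
    """Solve a program deterministically; map solver codes to plain statuses."""
    sign = -1.0 if p.sense == "max" else 1.0
    try:
        if p.is_mip:
            constraints = []
            if p.a_eq is not None:
                constraints.append(sopt.LinearConstraint(p.a_eq, p.b_eq, p.b_eq))
            if p.a_ub is not None:
                constraints.append(
                    sopt.LinearConstraint(p.a_ub, -np.inf, p.b_ub)
                )
            res = sopt.milp(
                c=sign * p.c,
                constraints=constraints,
                bounds=sopt.Bounds(p.bounds[:, 0], p.bounds[:, 1]),
                integrality=p.integrality,
            )
            status = _MILP_STATUS.get(res.status, "error")
        else:
            res = sopt.linprog(
                c=sign * p.c,
                A_eq=p.a_eq,
                b_eq=p.b_eq,
                A_ub=p.a_ub,
                b_ub=p.b_ub,
                bounds=p.bounds,
                method="highs",
            )
            status = _LINPROG_STATUS.get(res.status, "error")
    except Exception as exc:  # pragma: no cover - defensive
        return SolveResult("error", message=str(exc))
    if status != "optimal":
        return SolveResult(status, message=getattr(res, "message", ""))
    return SolveResult(
        "optimal",
        values=np.asarray(res.x, dtype=float),
        objective_value=sign * float(res.fun),
        message=getattr(res, "message", ""),
    )


def check_feasibility(p: LinearProgram) -> bool:
    """True iff the constraint block admits a solution (zero objective LP)."""
    probe = LinearProgram(
        c=np.zeros_like(p.c),
        bounds=p.bounds,
        a_eq=p.a_eq,
        b_eq=p.b_eq,
        a_ub=p.a_ub,
        b_ub=p.b_ub,
        integrality=p.integrality,
    )
    res = solve(probe)
    if res.status == "error":
        raise RuntimeError(f"solver failure during feasibility check: {res.message}")
    return res.status == "optimal"


def violation(p: LinearProgram, x: np.ndarray) -> float:
    """Largest constraint violation of ``x``, scaled by ``1 + |rhs|`` per row."""
    worst = 0.0
    x = np.asarray(x, dtype=float)
    if p.a_eq is not None:
        r = np.abs(p.a_eq @ x - p.b_eq) / (1.0 + np.abs(p.b_eq))
        worst = max(worst, float(r.max(initial=0.0)))
    if p.a_ub is not None:
        r = (p.a_ub @ x - p.b_ub) / (1.0 + np.abs(p.b_ub))
        worst = max(worst, float(r.max(initial=0.0)))
    worst = max(worst, float((p.bounds[:, 0] - x).max(initial=0.0)))
    worst = max(worst, float((x - p.bounds[:, 1]).max(initial=0.0)))
    return worst
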