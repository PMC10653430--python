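"""Thin deterministic LP/MILP layer on top of scipy's HiGHS bindings.

All optimisation in the package funnels through :func:`solve_lp` and
:func:`solve_milp` so that solver options (tolerances, determinism) are set
in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

__all__ = [
    "LPResult",
    "InfeasibleProblemError",
    "UnboundedProblemError",
    "SolverError",
    "solve_lp",
    "solve_milp",
]


class SolverError(RuntimeError):
    """Solver terminated abnormally (not optimal/infeasible/unbounded)."""


class InfeasibleProblemError(SolverError):
    """The optimisation problem has no feasible point."""


class UnboundedProblemError(SolverError):
    """The optimisation problem is unbounded."""


@dataclass
class LPResult:
    status: str              # "optimal" | "infeasible" | "unbounded"
    objective: float | None  # in the caller's sense (max problems un-negated)
    x: np.ndarray | None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


_LINPROG_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def solve_lp(
    c: np.ndarray,
    A_eq: sparse.spmatrix | np.ndarray | None,
    b_eq: np.ndarray | None,
    lb: np.ndarray,
    ub: np.ndarray,
    sense: str = "min",
    A_ub: sparse.spmatrix | np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
) -> LPResult:
    """Solve ``min/max c.x  s.t.  A_eq x = b_eq, A_ub x <= b_ub, lb <= x <= ub``."""
    if sense not in ("min", "max"):
        raise ValueError(f"sense must be 'min' or 'max', got {sense!r}")
    sign = 1.0 if sense == "min" else -1.0
    res = linprog(
        sign * np.asarray(c, dtype=float),
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    status = _LINPROG_STATUS.get(res.status)
    if status is None:
        raise SolverError(f"LP terminated abnormally: {res.message}")
    if status != "optimal":
        return LPResult(status, None, None)
    return LPResult("optimal", sign * res.fun, res.x)


_MILP_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def solve_milp(
    c: np.ndarray,
    integrality: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    constraints: list[LinearConstraint],
    sense: str = "min",
    mip_rel_gap: float = 0.0,
) -> LPResult:
    """Solve a MILP to proven optimality (gap 0 by default, single thread)."""
    if sense not in ("min", "max"):
        raise ValueError(f"sense must be 'min' or 'max', got {sense!r}")
    sign = 1.0 if sense == "min" else -1.0
    res = milp(
        sign * np.asarray(c, dtype=float),
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options={"mip_rel_gap": mip_rel_gap},
    )
    # scipy's milp reports status 1 ("iteration/time limit") only when limits
    # are set; we set none, so anything but 0/2/3 is a hard error.
    if res.status == 0:
        return LPResult("optimal", sign * res.fun, res.x)
    if res.status == 2:
        return LPResult("infeasible", None, None)
    if res.status == 3:
        return LPResult("unbounded", None, None)
    raise SolverError(f"MILP terminated abnormally: {res.message}")
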