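"""Thin wrappers around scipy's HiGHS LP/MILP interface.

All optimisation in the package flows through these two helpers so that solver
options (tolerances, time limits) are set in one place.  HiGHS is
deterministic in single-threaded operation, which is what makes set-level
reproducibility of the enumeration possible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

#: options for every MILP solve
MIP_OPTIONS = {
    "mip_rel_gap": 0.0,
    "presolve": True,
}


@dataclass
class SolveResult:
    status: str  # "optimal" | "infeasible" | "time_limit" | "error"
    x: np.ndarray | None
    objective: float | None
    message: str = ""


def solve_lp(
    c,
    A_ub=None,
    b_ub=None,
    A_eq=None,
    b_eq=None,
    bounds=None,
) -> SolveResult:
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    if res.status == 0:
        return SolveResult("optimal", res.x, res.fun, res.message)
    if res.status == 2:
        return SolveResult("infeasible", None, None, res.message)
    if res.status == 3:
        return SolveResult("unbounded", None, None, res.message)
    return SolveResult("error", None, None, res.message)


def solve_milp(
    c,
    A,
    lb,
    ub,
    integrality,
    bounds_lo,
    bounds_hi,
    time_limit_s: float | None = None,
) -> SolveResult:
    """Solve min c.x s.t. lb <= A x <= ub, bounds_lo <= x <= bounds_hi."""
    options = dict(MIP_OPTIONS)
    if time_limit_s is not None:
        options["time_limit"] = float(time_limit_s)
    A = sp.csr_matrix(A)
    res = milp(
        c=np.asarray(c, dtype=float),
        constraints=LinearConstraint(A, np.asarray(lb), np.asarray(ub)),
        integrality=np.asarray(integrality),
        bounds=Bounds(np.asarray(bounds_lo, dtype=float), np.asarray(bounds_hi, dtype=float)),
        options=options,
    )
    if res.status == 0:
        return SolveResult("optimal", res.x, res.fun, res.message)
    if res.status == 2:
        return SolveResult("infeasible", None, None, res.message)
    if res.status == 1:
        return SolveResult("time_limit", res.x, res.fun, res.message)
    return SolveResult("error", None, None, res.message)
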