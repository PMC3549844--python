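"""Thin LP/QP wrappers around scipy (HiGHS) and OSQP.

All optimization in the package funnels through these two helpers so that
solver settings (tolerances, determinism) are fixed in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog


class SolverError(RuntimeError):
    """A solve ended in a status the caller cannot use."""


@dataclass
class LPResult:
    x: np.ndarray
    fun: float
    status: str  # "optimal" | "infeasible" | "unbounded" | other


def solve_lp(
    c: np.ndarray,
    A: sp.spmatrix | None,
    row_lb: np.ndarray | None,
    row_ub: np.ndarray | None,
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
) -> LPResult:
    """Minimize c'x subject to row_lb <= A x <= row_ub and box bounds.

    Rows with row_lb == row_ub become equalities; one-sided rows use +-inf.
    """
    A_ub_rows, b_ub, A_eq_rows, b_eq = [], [], [], []
    if A is not None:
        A = sp.csr_matrix(A)
        row_lb = np.asarray(row_lb, float)
        row_ub = np.asarray(row_ub, float)
        eq = row_lb == row_ub
        if eq.any():
            A_eq_rows.append(A[eq])
            b_eq.append(row_lb[eq])
        up = ~eq & np.isfinite(row_ub)
        if up.any():
            A_ub_rows.append(A[up])
            b_ub.append(row_ub[up])
        lo = ~eq & np.isfinite(row_lb)
        if lo.any():
            A_ub_rows.append(-A[lo])
            b_ub.append(-row_lb[lo])
    kw = {}
    if A_ub_rows:
        kw["A_ub"] = sp.vstack(A_ub_rows)
        kw["b_ub"] = np.concatenate(b_ub)
    if A_eq_rows:
        kw["A_eq"] = sp.vstack(A_eq_rows)
        kw["b_eq"] = np.concatenate(b_eq)
    res = linprog(
        c,
        bounds=np.column_stack([bounds_lo, bounds_hi]),
        method="highs",
        **kw,
    )
    status = {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(res.status, "failed")
    x = res.x if res.x is not None else np.full(len(c), np.nan)
    return LPResult(x=x, fun=float(res.fun) if res.fun is not None else np.nan, status=status)


@dataclass
class QPResult:
    x: np.ndarray
    objective: float  # 0.5 x'Px + q'x
    status: str


def solve_qp(
    P: sp.spmatrix,
    q: np.ndarray,
    A: sp.spmatrix,
    l: np.ndarray,
    u: np.ndarray,
    *,
    eps: float = 1e-10,
    max_iter: int = 200_000,
) -> QPResult:
    """Minimize 0.5 x'Px + q'x subject to l <= A x <= u via OSQP (polished)."""
    import osqp

    solver = osqp.OSQP()
    solver.setup(
        sp.csc_matrix(P),
        np.asarray(q, float),
        sp.csc_matrix(A),
        np.asarray(l, float),
        np.asarray(u, float),
        verbose=False,
        eps_abs=eps,
        eps_rel=eps,
        eps_prim_inf=1e-9,
        eps_dual_inf=1e-9,
        max_iter=max_iter,
        polishing=True,
        scaled_termination=False,
    )
    res = solver.solve(raise_error=False)
    status = res.info.status
    if status in ("solved", "solved inaccurate"):
        st = "optimal"
    elif "infeasible" in status:
        st = "infeasible"
    else:
        st = "failed"
    x = res.x if res.x is not None else np.full(P.shape[0], np.nan)
    return QPResult(x=np.asarray(x, float), objective=float(res.info.obj_val), status=st)
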