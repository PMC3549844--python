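"""Piecewise-linear machinery for the inner MOMA objective.

Each reaction flux is written as a convex combination of grid endpoints,
v_j = sum_t beta_jt * v_j^t with sum_t beta_jt = 1, beta >= 0.  The convex
quadratic contribution (v_j - w_j)^2 is replaced by its chord,
sum_t (v_j^t - w_j)^2 beta_jt, which (dropping the constant w_j^2) gives the
linear cost coefficient v_jt^2 - 2 w_j v_jt per endpoint.  The chord always
over-estimates the quadratic (Jensen); the per-reaction overestimate at a
solution is the refinement gap Delta_j, and inserting the reconstructed
point as a new endpoint drives it to zero.

Grids always contain the bounds as first/last endpoints and, when inside
the bounds, 0 (so a knocked-out flux is exactly representable) and w_j (so
the wild type is exactly representable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from momaknock.network import MetabolicNetwork

__all__ = [
    "PiecewiseGrid",
    "RefinementRecord",
    "initial_grid",
    "cost_coeff",
    "cost_coefficients",
    "reconstruct",
    "slack_coefficients",
    "gap",
    "refine",
    "converged",
]


@dataclass
class PiecewiseGrid:
    """Per-reaction sorted endpoint arrays, in network reaction order."""

    reaction_ids: list[str]
    points: dict[str, np.ndarray]
    tol_merge_rel: float = 1e-9

    def __getitem__(self, rxn_id: str) -> np.ndarray:
        return self.points[rxn_id]

    def n_endpoints(self, rxn_id: str) -> int:
        return len(self.points[rxn_id])

    @property
    def total_endpoints(self) -> int:
        return sum(len(p) for p in self.points.values())

    def is_fixed(self, rxn_id: str) -> bool:
        """Degenerate grid of a fixed flux (lb == ub)."""
        return len(self.points[rxn_id]) == 1

    def validate(self) -> None:
        for rid, pts in self.points.items():
            if len(pts) < 1:
                raise ValueError(f"empty grid for {rid}")
            if np.any(np.diff(pts) <= 0):
                raise ValueError(f"grid for {rid} not strictly increasing")

    def copy(self) -> "PiecewiseGrid":
        return PiecewiseGrid(
            reaction_ids=list(self.reaction_ids),
            points={r: p.copy() for r, p in self.points.items()},
            tol_merge_rel=self.tol_merge_rel,
        )

    def to_tsv(self) -> str:
        lines = ["reaction_id\tendpoints"]
        for rid in self.reaction_ids:
            lines.append(rid + "\t" + ",".join(f"{p:.17g}" for p in self.points[rid]))
        return "\n".join(lines) + "\n"


def _merged_insert(pts: np.ndarray, value: float, tol: float) -> np.ndarray:
    """Insert ``value`` keeping strict order; no-op within ``tol`` of a point."""
    if np.any(np.abs(pts - value) <= tol):
        return pts
    return np.sort(np.append(pts, value))


def initial_grid(
    net: MetabolicNetwork,
    w: pd.Series,
    k_init: int = 4,
    *,
    v_glc_uptake: float | None = None,
) -> PiecewiseGrid:
    """Uniform ``k_init``-segment grid per reaction, then 0, w_j (and the
    fixed glucose rate) inserted as endpoints when strictly inside the bounds.

    A fixed flux (lb == ub) degenerates to a single-point grid and is
    excluded from refinement.
    """
    if k_init < 1:
        raise ValueError("k_init must be >= 1")
    points: dict[str, np.ndarray] = {}
    for j, rid in enumerate(net.reaction_ids):
        lo, hi = net.lb[j], net.ub[j]
        if hi - lo <= 0.0:
            points[rid] = np.array([lo])
            continue
        tol = 1e-9 * (hi - lo)
        pts = np.linspace(lo, hi, k_init + 1)
        for extra in (0.0, float(w[rid])):
            if lo < extra < hi:
                pts = _merged_insert(pts, extra, tol)
        if rid == net.glucose_rxn and v_glc_uptake is not None:
            if lo < v_glc_uptake < hi:
                pts = _merged_insert(pts, float(v_glc_uptake), tol)
        points[rid] = pts
    grid = PiecewiseGrid(reaction_ids=list(net.reaction_ids), points=points)
    grid.validate()
    return grid


def cost_coeff(grid: PiecewiseGrid, w: pd.Series, rxn_id: str, t: int) -> float:
    """Linearized cost coefficient of endpoint t: v_jt^2 - 2 w_j v_jt."""
    v = grid[rxn_id][t]
    return float(v * v - 2.0 * float(w[rxn_id]) * v)


def cost_coefficients(grid: PiecewiseGrid, w: pd.Series) -> dict[str, np.ndarray]:
    """Vectorized cost coefficients for all reactions."""
    out = {}
    for rid in grid.reaction_ids:
        v = grid[rid]
        out[rid] = v * v - 2.0 * float(w[rid]) * v
    return out


def slack_coefficients(grid: PiecewiseGrid) -> dict[str, np.ndarray]:
    """Per-endpoint chord-error budgets sigma_jt.

    The chord of (v - w)^2 over a segment of width W overestimates the
    quadratic by at most (W/2)^2 (attained at the midpoint, independent of
    w).  Assigning each endpoint the worst adjacent-segment budget,
    sigma_jt = (max(W_{t-1}, W_t)/2)^2, guarantees that any flux written as
    a convex combination of the two endpoints of its segment receives slack
    at least equal to its true chordal error.  Used to relax the
    strong-duality row into a valid upper-bounding constraint.
    """
    out = {}
    for rid in grid.reaction_ids:
        pts = grid[rid]
        if len(pts) < 2:
            out[rid] = np.zeros(len(pts))
            continue
        W = np.diff(pts)
        left = np.concatenate([[W[0]], W])
        right = np.concatenate([W, [W[-1]]])
        out[rid] = (np.maximum(left, right) / 2.0) ** 2
    return out


def reconstruct(grid: PiecewiseGrid, beta: dict[str, np.ndarray]) -> pd.Series:
    """Fluxes from convex-combination coefficients: v_j = sum_t beta_jt v_j^t."""
    vals = []
    for rid in grid.reaction_ids:
        b = np.asarray(beta[rid], float)
        pts = grid[rid]
        if len(b) != len(pts):
            raise ValueError(f"beta length mismatch for {rid}")
        vals.append(float(b @ pts))
    return pd.Series(vals, index=grid.reaction_ids, name="reconstructed")


@dataclass
class RefinementRecord:
    """Per-reaction linearization diagnostics at one solution.

    delta: chordal overestimate of the quadratic cost (flux^2 units),
    >= 0 up to numerical noise by convexity.  max_beta: largest convex
    coefficient (1 means the flux sits exactly on an endpoint).
    insert_at: reconstructed flux, the endpoint refinement would add.
    """

    reaction_ids: list[str]
    delta: dict[str, float]
    max_beta: dict[str, float]
    insert_at: dict[str, float]
    excluded: frozenset[str] = frozenset()

    @property
    def max_delta(self) -> float:
        vals = [d for r, d in self.delta.items() if r not in self.excluded]
        return max(vals, default=0.0)

    @property
    def min_max_beta(self) -> float:
        vals = [b for r, b in self.max_beta.items() if r not in self.excluded]
        return min(vals, default=1.0)


def gap(
    grid: PiecewiseGrid,
    beta: dict[str, np.ndarray],
    w: pd.Series,
    *,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> RefinementRecord:
    """Per-reaction linearization gap at a convex-combination solution.

    For the generic case (any valid beta) the gap is the generalized form
    ``sum_t (v_jt - w_j)^2 beta_jt - (v_hat_j - w_j)^2`` with v_hat the
    reconstructed flux; when beta has exactly two adjacent nonzeros this
    coincides with the textbook two-endpoint expression.  Reactions in
    ``exclude`` (the target, whose inner-cost coefficient is zero, and fixed
    fluxes) report a zero gap.
    """
    delta, max_beta, insert_at = {}, {}, {}
    excluded = frozenset(exclude) | frozenset(
        r for r in grid.reaction_ids if grid.is_fixed(r)
    )
    for rid in grid.reaction_ids:
        pts = grid[rid]
        b = np.asarray(beta[rid], float)
        if grid.is_fixed(rid):
            delta[rid] = 0.0
            max_beta[rid] = 1.0
            insert_at[rid] = float(pts[0])
            continue
        wj = float(w[rid])
        v_hat = float(b @ pts)
        lin = float(b @ (pts - wj) ** 2)
        delta[rid] = lin - (v_hat - wj) ** 2
        max_beta[rid] = float(b.max())
        insert_at[rid] = v_hat
    return RefinementRecord(
        reaction_ids=list(grid.reaction_ids),
        delta=delta,
        max_beta=max_beta,
        insert_at=insert_at,
        excluded=excluded,
    )


def converged(record: RefinementRecord, eps: float, theta: float) -> bool:
    """True iff every (non-excluded) reaction has gap < eps and its largest
    convex coefficient above theta — the flux effectively sits on an endpoint
    and the chord is exact there."""
    for rid in record.reaction_ids:
        if rid in record.excluded:
            continue
        if not (record.delta[rid] < eps and record.max_beta[rid] > theta):
            return False
    return True


def refine(
    grid: PiecewiseGrid,
    record: RefinementRecord,
    eps: float,
    theta: float,
) -> tuple[PiecewiseGrid, int]:
    """Insert the reconstructed point for each reaction failing the
    convergence test; returns (new grid, number of endpoints added).

    Bounds endpoints are never touched; insertions within the merge
    tolerance of an existing endpoint are skipped, so refinement of a
    converged grid is a no-op.
    """
    new = grid.copy()
    added = 0
    for rid in grid.reaction_ids:
        if rid in record.excluded:
            continue
        if record.delta[rid] < eps and record.max_beta[rid] > theta:
            continue
        pts = new.points[rid]
        tol = grid.tol_merge_rel * (pts[-1] - pts[0])
        merged = _merged_insert(pts, record.insert_at[rid], tol)
        if len(merged) > len(pts):
            new.points[rid] = merged
            added += 1
    new.validate()
    return new, added
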