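"""Adaptive refinement driver: MILP solve -> gap evaluation -> grid
refinement, iterated until the piecewise linearization is exact at the
optimum.

The single-level MILP is assembled with the strong-duality row relaxed by
the per-segment chord-error budget, which makes its optimum a valid *upper
bound* on the bi-level optimum for every knockout pattern, seen or unseen
(the plain chordal equality can both over- and under-rate the optimistic
target of a pattern the iteration has not visited).  The driver exploits
that one-sidedness as a candidate-generation loop:

1. solve the relaxed MILP, restricted by no-good cuts to knockout sets not
   yet evaluated and by a cut requiring improvement on the incumbent;
2. evaluate the proposed set exactly (MOMA QP with the optimistic
   tie-break) — this value is achievable, hence a valid lower bound objL —
   update the incumbent, insert the exact inner optimum's coordinates as
   grid endpoints, and exclude the set;
3. terminate when the MILP proves that no unevaluated set can beat the
   incumbent (infeasible, or optimum within tolerance of it): since the
   relaxed value dominates the exact value, the incumbent is then the
   certified bi-level optimum.

A final restriction solve — binaries frozen to the winning set, duality row
as a plain equality, on a grid that contains that set's exact inner optimum
— reproduces the converged state the adaptive linearization aims for: every
chordal gap Delta_j vanishes, every beta_j concentrates on an endpoint, and
the MILP outer objective coincides with the exact QP re-evaluation.
Per-reaction chordal refinement (insert the reconstructed flux wherever
Delta_j > eps or beta_j is spread) still runs on every candidate iterate,
tightening the relaxation as the loop proceeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from momaknock.bilevel import solve_with_bigm_retry
from momaknock.network import MetabolicNetwork, ProblemSpec
from momaknock.pwl import (
    PiecewiseGrid,
    converged,
    gap,
    initial_grid,
    refine,
    slack_coefficients,
)
from momaknock.steady_state import MOMAReport, solve_fba, solve_moma

__all__ = ["SolverConfig", "IterationRecord", "KnockoutResult", "warm_bound", "run_momaknock"]


@dataclass
class SolverConfig:
    """Tunables of the adaptive bi-level solver.

    eps is the absolute gap threshold; when None it is scaled to the problem
    as 1e-6 * (1 + ||w||_2^2).  theta close to 1 demands that each flux sit
    (essentially) on a grid endpoint at termination.
    """

    k_init: int = 4
    eps: float | None = None
    theta: float = 0.999
    M_val: float | None = None
    max_iter: int = 100
    tol_obj_rel: float = 1e-6
    time_limit: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.eps is not None and self.eps <= 0:
            raise ValueError("eps must be > 0")
        if not (0.0 < self.theta < 1.0):
            raise ValueError("theta must lie in (0, 1)")


@dataclass
class IterationRecord:
    iteration: int
    milp_objective: float
    objL: float
    max_delta: float
    min_max_beta: float
    total_endpoints: int
    endpoints_added: int
    knockouts: tuple[str, ...]
    cut_used: bool
    milp_status: str


@dataclass
class KnockoutResult:
    """Outcome of the adaptive solve.

    ``outer_objective`` is the final MILP value; ``moma`` is the exact-QP
    re-evaluation of the returned knockout set (the two agree at
    convergence).  ``status`` records which termination test fired.
    """

    knockouts: frozenset[str]
    outer_objective: float
    moma: MOMAReport
    status: str
    trace: list[IterationRecord] = field(default_factory=list)
    wild_type: pd.Series | None = None
    final_record: "object | None" = None  # RefinementRecord of the last solve
    final_grid: PiecewiseGrid | None = None

    @property
    def n_iterations(self) -> int:
        return len(self.trace)


_NEG_INF = float("-inf")


def _refine_slack(
    old_grid: PiecewiseGrid,
    new_grid: PiecewiseGrid,
    beta: dict[str, np.ndarray],
    eps: float,
    target_rxn: str,
) -> int:
    """Split segments adjacent to endpoints whose chord-error budget the
    MILP actually consumed; mutates ``new_grid``, returns endpoints added.

    The upper-bounding relaxation lets a solution sit on an endpoint while
    claiming that endpoint's slack sigma_jt; halving the neighboring
    segments quarters the budget there, so repeated splitting removes the
    incentive geometrically.  ``beta`` indexes ``old_grid`` (the grid the
    MILP was solved on).
    """
    added = 0
    sig_all = slack_coefficients(old_grid)
    for rid in old_grid.reaction_ids:
        if rid == target_rxn or old_grid.is_fixed(rid):
            continue
        pts = old_grid.points[rid]
        b = np.asarray(beta[rid], float)
        if float(b @ sig_all[rid]) <= eps:
            continue
        cur = new_grid.points[rid]
        tol = new_grid.tol_merge_rel * (cur[-1] - cur[0])
        segments = set()
        for t in np.nonzero(b > 1e-9)[0]:
            if t > 0:
                segments.add((pts[t - 1], pts[t]))
            if t < len(pts) - 1:
                segments.add((pts[t], pts[t + 1]))
        for a_pt, b_pt in segments:
            for mid in np.linspace(a_pt, b_pt, 3)[1:-1]:
                if np.all(np.abs(cur - mid) > tol):
                    cur = np.sort(np.append(cur, mid))
                    added += 1
        new_grid.points[rid] = cur
    return added


def _restriction_grid(
    net: MetabolicNetwork, w: pd.Series, flux: pd.Series, v_glc_uptake: float
) -> PiecewiseGrid:
    """Minimal grid for the final restriction solve: per reaction the
    bounds, 0, the wild-type flux and the winning set's exact inner-optimal
    flux.  Keeping the grid this small avoids near-duplicate endpoints
    (inserted by different QP solves over the iterations) over which an
    optimal basis could spread its convex coefficients microscopically.
    """
    points: dict[str, np.ndarray] = {}
    for j, rid in enumerate(net.reaction_ids):
        lo, hi = net.lb[j], net.ub[j]
        if hi - lo <= 0.0:
            points[rid] = np.array([lo])
            continue
        pts = np.array([lo, hi])
        v_star = float(np.clip(flux[rid], lo, hi))
        tol = 1e-6 * (1.0 + max(abs(lo), abs(hi)))
        if np.all(np.abs(pts - v_star) > tol):
            pts = np.sort(np.append(pts, v_star))
        for extra in (0.0, float(w[rid]), v_glc_uptake if rid == net.glucose_rxn else 0.0):
            if lo < extra < hi and np.all(np.abs(pts - extra) > tol):
                pts = np.sort(np.append(pts, extra))
        points[rid] = pts
    grid = PiecewiseGrid(reaction_ids=list(net.reaction_ids), points=points)
    grid.validate()
    return grid


def _insert_exact_point(grid: PiecewiseGrid, flux: pd.Series) -> int:
    """Insert each reaction's exact inner-optimal flux as a grid endpoint
    (in place); returns how many endpoints were added."""
    added = 0
    for rid in grid.reaction_ids:
        if grid.is_fixed(rid):
            continue
        pts = grid.points[rid]
        v = float(np.clip(flux[rid], pts[0], pts[-1]))
        tol = grid.tol_merge_rel * (pts[-1] - pts[0])
        if np.all(np.abs(pts - v) > tol):
            grid.points[rid] = np.sort(np.append(pts, v))
            added += 1
    return added


def warm_bound(
    net: MetabolicNetwork,
    w: pd.Series,
    prev_knockouts: frozenset[str] | None,
    spec: ProblemSpec,
) -> float:
    """Exact (QP) optimistic target flux of the previous iteration's
    knockouts — an achievable outer value, hence a valid lower bound on the
    bi-level optimum.  Returns -inf when there is no usable previous set."""
    if prev_knockouts is None:
        return _NEG_INF
    rep = solve_moma(net, w, prev_knockouts, spec, exclude_target=True)
    if not rep.feasible:
        return _NEG_INF
    return rep.target_flux


def run_momaknock(
    net: MetabolicNetwork,
    spec: ProblemSpec,
    config: SolverConfig | None = None,
    *,
    w: pd.Series | None = None,
) -> KnockoutResult:
    """Find <= K knockouts maximizing the MOMA-constrained target flux.

    The wild-type reference is computed by FBA (with the minimum-norm
    tie-break) unless supplied.  The returned knockout set is always the
    incumbent with the best *exact* QP evaluation seen across iterations.
    """
    config = config or SolverConfig()
    net.validate(spec)
    if w is None:
        w = solve_fba(net, spec)
    eps = config.eps if config.eps is not None else 1e-6 * (1.0 + float(w @ w))
    grid = initial_grid(net, w, config.k_init, v_glc_uptake=spec.v_glc_uptake)
    exclude = frozenset({net.target_rxn})

    trace: list[IterationRecord] = []
    best: tuple[float, frozenset[str], MOMAReport] | None = None
    evaluated: list[frozenset[str]] = []
    status = "max_iter"

    # seed the incumbent with the always-feasible empty knockout set
    objL0 = warm_bound(net, w, frozenset(), spec)
    if np.isfinite(objL0):
        rep0 = solve_moma(net, w, frozenset(), spec, exclude_target=True)
        best = (rep0.target_flux, frozenset(), rep0)
        _insert_exact_point(grid, rep0.flux)
    evaluated.append(frozenset())

    for it in range(1, config.max_iter + 1):
        objL = best[0] if best is not None else _NEG_INF
        improve = (
            objL + config.tol_obj_rel * (1.0 + abs(objL))
            if np.isfinite(objL)
            else None
        )
        sol, model = solve_with_bigm_retry(
            net, w, grid, spec,
            M_val=config.M_val,
            lower_bound=improve,
            seed=config.seed,
            time_limit=config.time_limit,
            nogood_sets=evaluated,
        )
        if sol.status == "infeasible":
            # no unevaluated knockout set can beat the incumbent even in the
            # upper-bounding relaxation: the incumbent is certified optimal
            status = "converged"
            break
        if not sol.feasible:
            if best is not None:
                status = "milp_" + sol.status
                break
            raise RuntimeError(
                f"bi-level MILP {sol.status} (big-M audit "
                f"{'ok' if sol.bigm_ok else 'FAILED'}, M={sol.M_val:g}); "
                "check the problem spec"
            )
        knockouts = sol.knockouts
        record = gap(grid, sol.beta, w, exclude=exclude)
        exact = solve_moma(net, w, knockouts, spec, exclude_target=True)
        evaluated.append(knockouts)
        new_grid, added = refine(grid, record, eps, config.theta)
        added += _refine_slack(grid, new_grid, sol.beta, eps, net.target_rxn)
        if exact.feasible:
            added += _insert_exact_point(new_grid, exact.flux)
            if best is None or exact.target_flux > best[0]:
                best = (exact.target_flux, knockouts, exact)
        grid = new_grid
        trace.append(
            IterationRecord(
                iteration=it,
                milp_objective=sol.outer_objective,
                objL=objL,
                max_delta=record.max_delta,
                min_max_beta=record.min_max_beta,
                total_endpoints=grid.total_endpoints,
                endpoints_added=added,
                knockouts=tuple(sorted(knockouts)),
                cut_used=improve is not None,
                milp_status=sol.status,
            )
        )
        if best is not None and sol.outer_objective <= best[0] + config.tol_obj_rel * (
            1.0 + abs(best[0])
        ):
            # the relaxation itself cannot improve on the incumbent
            status = "converged"
            break

    if best is None:
        raise RuntimeError("no feasible knockout set found (wild type infeasible?)")

    # parsimony/adjustment tie-break: a knockout that does not change the
    # achievable target is dropped, preferring among value-ties the strain
    # closest to the wild type (the minimal-adjustment philosophy)
    tie_tol = config.tol_obj_rel * (1.0 + abs(best[0]))
    from itertools import combinations as _combos

    base = sorted(best[1])
    for r in range(len(base)):
        for sub in _combos(base, r):
            rep = solve_moma(net, w, frozenset(sub), spec, exclude_target=True)
            if (
                rep.feasible
                and rep.target_flux >= best[0] - tie_tol
                and (
                    rep.l2_distance < best[2].l2_distance - 1e-9
                    or (
                        abs(rep.l2_distance - best[2].l2_distance) <= 1e-9
                        and len(sub) < len(best[1])
                    )
                )
            ):
                best = (max(best[0], rep.target_flux), frozenset(sub), rep)

    # final restriction solve: binaries frozen to the winner, plain duality
    # equality, exact inner optimum on a minimal purpose-built grid ->
    # chordal gaps vanish, beta concentrates, and the MILP outer objective
    # equals the exact QP value
    fin_grid = _restriction_grid(net, w, best[2].flux, spec.v_glc_uptake)
    sol_f, _ = solve_with_bigm_retry(
        net, w, fin_grid, spec,
        M_val=config.M_val,
        seed=config.seed,
        time_limit=config.time_limit,
        duality_slack=False,
        fixed_y=best[1],
    )
    record_f = None
    if sol_f.feasible:
        record_f = gap(fin_grid, sol_f.beta, w, exclude=exclude)
        milp_obj = sol_f.outer_objective
        trace.append(
            IterationRecord(
                iteration=len(trace) + 1,
                milp_objective=milp_obj,
                objL=best[0],
                max_delta=record_f.max_delta,
                min_max_beta=record_f.min_max_beta,
                total_endpoints=fin_grid.total_endpoints,
                endpoints_added=0,
                knockouts=tuple(sorted(best[1])),
                cut_used=False,
                milp_status="restriction",
            )
        )
        if status == "converged" and not converged(record_f, eps, config.theta):
            status = "converged_unconcentrated"
    else:
        milp_obj = best[0]

    return KnockoutResult(
        knockouts=best[1],
        outer_objective=milp_obj,
        moma=best[2],
        status=status,
        trace=trace,
        wild_type=w,
        final_record=record_f,
        final_grid=fin_grid if sol_f.feasible else grid,
    )
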