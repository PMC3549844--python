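"""LP/QP phenotype computations: FBA wild type, MOMA knockout evaluation,
and theoretical flux maxima.

The wild-type reference ``w`` is the growth-maximal flux distribution at a
fixed substrate uptake.  Because biomass-optimal vertices are typically
degenerate, FBA alone does not pin ``w`` down; a second stage minimizes
||v||_2 among biomass-optimal fluxes so that ``w`` is unique and
reproducible (disable with ``minimize_norm=False``).

MOMA predicts a knockout mutant's phenotype as the feasible flux vector
minimizing the squared Euclidean distance to ``w``.  When the target
reaction is excluded from that objective (as it is inside the bi-level
design problem), the inner optimum leaves the target flux undetermined; the
evaluation therefore finishes with an *optimistic* step that maximizes the
target flux among inner-optimal vectors, matching the tie-break implicit in
the duality-based single-level reformulation.  The MOMA objective is
strictly convex in every non-target flux, so the inner-optimal set fixes
those coordinates; the optimistic step is the LP max of v_target with the
non-target fluxes confined to a tight box around their unique optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from momaknock._lp import solve_lp, solve_qp
from momaknock.network import MetabolicNetwork, ProblemSpec

__all__ = [
    "InfeasibleModelError",
    "MOMAReport",
    "solve_fba",
    "solve_moma",
    "theoretical_max",
]

#: mass-balance residual tolerance ||S v||_inf <= tol_balance * max(1, ||v||_inf)
TOL_BALANCE = 1e-6

#: box half-width (relative) used by the optimistic target-flux stage
TOL_OPT = 1e-7


class InfeasibleModelError(RuntimeError):
    """The steady-state constraint set is empty (or growth is impossible)."""


@dataclass
class MOMAReport:
    """MOMA evaluation of one knockout set.

    moma_objective is sum over the objective reactions of (v_j - w_j)^2
    (target excluded when ``exclude_target``); l2_distance is ||v - w||_2
    over *all* reactions, the "v-wL2" column of the comparison tables.
    """

    status: str  # "optimal" | "infeasible"
    knockouts: frozenset[str]
    flux: pd.Series | None = None
    moma_objective: float = np.nan
    target_flux: float = np.nan
    biomass_flux: float = np.nan
    l2_distance: float = np.nan
    exclude_target: bool = True

    @property
    def feasible(self) -> bool:
        return self.status == "optimal"


def _knockout_bounds(
    net: MetabolicNetwork, knockouts: frozenset[str] | set[str]
) -> tuple[np.ndarray, np.ndarray]:
    lb, ub = net.lb.copy(), net.ub.copy()
    for rid in knockouts:
        j = net.rxn_idx(rid)
        lb[j] = 0.0
        ub[j] = 0.0
    return lb, ub


def _steady_state_rows(
    net: MetabolicNetwork, spec: ProblemSpec, lb: np.ndarray, ub: np.ndarray
):
    """Constraint rows shared by all phenotype problems:
    S v = 0, v_glc = uptake, v_biom >= floor, box bounds as identity rows."""
    M = net.n_reactions
    glc_row = sp.csr_matrix(
        (np.ones(1), (np.zeros(1, int), [net.glucose_idx])), shape=(1, M)
    )
    biom_row = sp.csr_matrix(
        (np.ones(1), (np.zeros(1, int), [net.biomass_idx])), shape=(1, M)
    )
    A = sp.vstack([net.S, glc_row, biom_row, sp.eye(M, format="csr")])
    N = net.n_metabolites
    lo = np.concatenate([np.zeros(N), [spec.v_glc_uptake, spec.v_biom_target], lb])
    hi = np.concatenate([np.zeros(N), [spec.v_glc_uptake, np.inf], ub])
    return A, lo, hi


def _check_balance(net: MetabolicNetwork, v: np.ndarray) -> None:
    resid = np.abs(net.S @ v).max() if net.n_metabolites else 0.0
    scale = max(1.0, np.abs(v).max())
    if resid > TOL_BALANCE * scale:
        raise RuntimeError(f"steady-state residual {resid:.2e} exceeds tolerance")


def solve_fba(
    net: MetabolicNetwork,
    spec: ProblemSpec,
    *,
    minimize_norm: bool = True,
) -> pd.Series:
    """Wild-type flux reference: maximize biomass, then (by default) pick the
    minimum-norm flux among biomass-optimal ones so the reference is unique.

    Raises InfeasibleModelError when the model is infeasible at the fixed
    uptake or cannot reach the minimum biomass.
    """
    M = net.n_reactions
    A, lo, hi = _steady_state_rows(net, spec, net.lb, net.ub)
    c = np.zeros(M)
    c[net.biomass_idx] = -1.0
    res = solve_lp(c, A, lo, hi, np.full(M, -np.inf), np.full(M, np.inf))
    if res.status == "unbounded":
        raise InfeasibleModelError("biomass flux is unbounded")
    if res.status != "optimal":
        raise InfeasibleModelError(
            "FBA infeasible: no steady state at the fixed glucose uptake "
            "meets the minimum biomass (infeasible/zero growth)"
        )
    biom_max = -res.fun
    v = res.x
    if minimize_norm:
        # second stage: min ||v||^2 with biomass pinned at its maximum
        lb2, ub2 = net.lb.copy(), net.ub.copy()
        lb2[net.biomass_idx] = biom_max
        ub2[net.biomass_idx] = biom_max
        A2, lo2, hi2 = _steady_state_rows(net, spec, lb2, ub2)
        qp = solve_qp(2.0 * sp.eye(M, format="csc"), np.zeros(M), A2, lo2, hi2)
        if qp.status == "optimal":
            v = qp.x
    _check_balance(net, v)
    return pd.Series(v, index=net.reaction_ids, name="wild_type")


def theoretical_max(net: MetabolicNetwork, rxn: str, spec: ProblemSpec) -> float:
    """LP maximum of one reaction's flux subject to steady state, bounds,
    the fixed glucose uptake and the minimum-biomass floor."""
    M = net.n_reactions
    A, lo, hi = _steady_state_rows(net, spec, net.lb, net.ub)
    c = np.zeros(M)
    c[net.rxn_idx(rxn)] = -1.0
    res = solve_lp(c, A, lo, hi, np.full(M, -np.inf), np.full(M, np.inf))
    if res.status == "unbounded":
        raise InfeasibleModelError(f"flux of {rxn!r} is unbounded")
    if res.status != "optimal":
        raise InfeasibleModelError("model infeasible under the given spec")
    return -res.fun


def solve_moma(
    net: MetabolicNetwork,
    w: pd.Series,
    knockouts: frozenset[str] | set[str],
    spec: ProblemSpec,
    exclude_target: bool = True,
) -> MOMAReport:
    """MOMA phenotype of a knockout set, with the optimistic target tie-break.

    Solves  min sum_{j in Obj} (v_j - w_j)^2  over the post-knockout steady
    states, Obj = all reactions (minus the target when ``exclude_target``).
    Infeasible (lethal) designs are reported via ``status``, not raised, so
    batch comparisons do not abort.
    """
    knockouts = frozenset(knockouts)
    for rid in knockouts:
        net.rxn_idx(rid)  # raises on unknown id
    M = net.n_reactions
    w_arr = np.asarray(w.reindex(net.reaction_ids), float)
    if np.isnan(w_arr).any():
        raise ValueError("wild-type reference does not cover all reactions")
    lb, ub = _knockout_bounds(net, knockouts)
    weights = np.ones(M)
    if exclude_target:
        weights[net.target_idx] = 0.0
    P = 2.0 * sp.diags(weights, format="csc")
    q = -2.0 * weights * w_arr
    A, lo, hi = _steady_state_rows(net, spec, lb, ub)
    qp = solve_qp(P, q, A, lo, hi)
    if qp.status != "optimal":
        return MOMAReport(status="infeasible", knockouts=knockouts, exclude_target=exclude_target)
    v = qp.x
    if exclude_target:
        v = _optimistic_target(net, spec, lb, ub, v)
    _check_balance(net, v)
    obj = float(np.sum(weights * (v - w_arr) ** 2))
    flux = pd.Series(v, index=net.reaction_ids, name="moma")
    return MOMAReport(
        status="optimal",
        knockouts=knockouts,
        flux=flux,
        moma_objective=obj,
        target_flux=float(v[net.target_idx]),
        biomass_flux=float(v[net.biomass_idx]),
        l2_distance=float(np.linalg.norm(v - w_arr)),
        exclude_target=exclude_target,
    )


def _optimistic_target(
    net: MetabolicNetwork,
    spec: ProblemSpec,
    lb: np.ndarray,
    ub: np.ndarray,
    v_star: np.ndarray,
) -> np.ndarray:
    """Maximize the target flux over inner-optimal vectors.

    The inner objective is strictly convex in the non-target fluxes, so they
    are unique at the optimum; box them within a tolerance of v* and solve
    the remaining LP for the target flux.
    """
    M = net.n_reactions
    t = net.target_idx
    delta = TOL_OPT * (1.0 + np.abs(v_star))
    lo_box = np.maximum(lb, v_star - delta)
    hi_box = np.minimum(ub, v_star + delta)
    lo_box[t], hi_box[t] = lb[t], ub[t]
    A, lo, hi = _steady_state_rows(net, spec, lo_box, hi_box)
    c = np.zeros(M)
    c[t] = -1.0
    res = solve_lp(c, A, lo, hi, np.full(M, -np.inf), np.full(M, np.inf))
    if res.status != "optimal":
        # numerical box too tight for the LP; fall back to the QP point
        return v_star
    return res.x
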