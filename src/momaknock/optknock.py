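"""Growth-inner (OptKnock-style) comparator.

The classical strain-design bi-level problem keeps the growth-maximization
inner LP: the mutant is assumed to grow optimally after the knockout.  LP
duality collapses it into a single-level MILP directly (no linearization is
needed — the inner objective is already linear).  Designs are then
re-evaluated under the MOMA objective, which is the comparison protocol
that exposes how far growth-optimal designs drift from the wild type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint
from scipy.optimize import milp as scipy_milp

from momaknock.network import MetabolicNetwork, ProblemSpec
from momaknock.steady_state import MOMAReport, solve_fba, solve_moma

__all__ = ["BaselineResult", "run_optknock", "compare_strategies"]


@dataclass
class BaselineResult:
    """OptKnock design plus its MOMA re-evaluation.

    design_target / design_biomass are the fluxes the growth-inner MILP
    predicts (optimistic tie-break among growth-optimal fluxes); ``moma``
    holds the phenotype the MOMA model predicts for the same deletions.
    """

    knockouts: frozenset[str]
    design_target: float
    design_biomass: float
    moma: MOMAReport
    status: str = "optimal"


def _assemble_optknock(net: MetabolicNetwork, spec: ProblemSpec, M_val: float):
    """Single-level MILP: outer max v_target, inner max v_biomass via duality.

    Variables: v (M), y (M), lam (N), mu (glucose dual), nu (biomass-floor
    dual, >=0), p/q (bound duals, >=0), e/f (p*y, q*y big-M products).
    """
    M, N = net.n_reactions, net.n_metabolites
    iv = 0
    iy = M
    il = 2 * M
    imu = 2 * M + N
    inu = imu + 1
    ip = inu + 1
    iq = ip + M
    ie = iq + M
    if_ = ie + M
    n = if_ + M

    rows, lo, hi = [], [], []

    def add(r, l, h):
        rows.append(sp.csr_matrix(r))
        lo.extend(np.atleast_1d(l))
        hi.extend(np.atleast_1d(h))

    # primal: S v = 0
    add(sp.hstack([net.S, sp.csr_matrix((N, n - M))]), np.zeros(N), np.zeros(N))
    glc = sp.lil_matrix((1, n))
    glc[0, iv + net.glucose_idx] = 1.0
    add(glc, spec.v_glc_uptake, spec.v_glc_uptake)
    biom = sp.lil_matrix((1, n))
    biom[0, iv + net.biomass_idx] = 1.0
    add(biom, spec.v_biom_target, np.inf)
    arange = np.arange(M)
    gate_ub = sp.csr_matrix(
        (np.concatenate([np.ones(M), -net.ub]), (np.tile(arange, 2), np.concatenate([arange, iy + arange]))),
        shape=(M, n),
    )
    add(gate_ub, np.full(M, -np.inf), np.zeros(M))
    gate_lb = sp.csr_matrix(
        (np.concatenate([np.ones(M), -net.lb]), (np.tile(arange, 2), np.concatenate([arange, iy + arange]))),
        shape=(M, n),
    )
    add(gate_lb, np.zeros(M), np.full(M, np.inf))
    cand_idx = [net.rxn_idx(r) for r in sorted(net.knockout_candidates)]
    budget = sp.csr_matrix(
        (np.ones(len(cand_idx)), (np.zeros(len(cand_idx), int), [iy + j for j in cand_idx])),
        shape=(1, n),
    )
    add(budget, len(cand_idx) - spec.K, np.inf)

    # dual feasibility (equalities, inner objective min -v_biom):
    # S'lam + e_glc mu + e_biom nu + p - q = -e_biom
    D = sp.lil_matrix((M, n))
    ST = net.S.T.tocoo()
    for j, i, s in zip(ST.row, ST.col, ST.data):
        D[j, il + i] = s
    D[net.glucose_idx, imu] = 1.0
    D[net.biomass_idx, inu] = 1.0
    for j in range(M):
        D[j, ip + j] = 1.0
        D[j, iq + j] = -1.0
    rhs = np.zeros(M)
    rhs[net.biomass_idx] = -1.0
    add(D, rhs, rhs)

    # strong duality: -v_biom = u*mu + btgt*nu + sum lb_j e_j - sum ub_j f_j
    sd = sp.lil_matrix((1, n))
    sd[0, iv + net.biomass_idx] = -1.0
    sd[0, imu] = -spec.v_glc_uptake
    sd[0, inu] = -spec.v_biom_target
    for j in range(M):
        sd[0, ie + j] = -net.lb[j]
        sd[0, if_ + j] = net.ub[j]
    add(sd, 0.0, 0.0)

    # big-M product rows
    for dual0, prod0 in ((ip, ie), (iq, if_)):
        for j in range(M):
            r = sp.lil_matrix((4, n))
            r[0, prod0 + j] = 1.0
            r[0, iy + j] = -M_val
            r[1, prod0 + j] = 1.0
            r[1, iy + j] = M_val
            r[2, prod0 + j] = 1.0
            r[2, dual0 + j] = -1.0
            r[2, iy + j] = M_val
            r[3, prod0 + j] = 1.0
            r[3, dual0 + j] = -1.0
            r[3, iy + j] = -M_val
            add(r, [-np.inf, 0.0, -np.inf, -M_val], [0.0, np.inf, M_val, np.inf])

    A = sp.vstack(rows, format="csr")
    var_lb = np.full(n, -np.inf)
    var_ub = np.full(n, np.inf)
    integrality = np.zeros(n)
    cand = net.knockout_candidates
    for j, rid in enumerate(net.reaction_ids):
        if rid in cand:
            var_lb[iy + j], var_ub[iy + j] = 0.0, 1.0
            integrality[iy + j] = 1
        else:
            var_lb[iy + j], var_ub[iy + j] = 1.0, 1.0
    var_lb[inu] = 0.0
    var_lb[ip : ip + M] = 0.0
    var_lb[iq : iq + M] = 0.0

    c = np.zeros(n)
    c[iv + net.target_idx] = -1.0
    idx = {"v": iv, "y": iy, "p": ip, "q": iq, "e": ie, "f": if_}
    return A, np.array(lo), np.array(hi), var_lb, var_ub, integrality, c, idx


def run_optknock(
    net: MetabolicNetwork,
    spec: ProblemSpec,
    K: int | None = None,
    *,
    M_val: float = 1e3,
    w: pd.Series | None = None,
    time_limit: float | None = None,
    max_retries: int = 3,
) -> BaselineResult:
    """OptKnock design for a budget of K knockouts, MOMA re-evaluated.

    The MILP's duality construction implicitly applies the optimistic
    tie-break: among growth-optimal mutant fluxes, the one maximizing the
    target is reported as the design phenotype.
    """
    if K is not None and K != spec.K:
        spec = ProblemSpec(spec.v_glc_uptake, spec.v_biom_target, K)
    net.validate(spec)
    if w is None:
        w = solve_fba(net, spec)
    M_cur = M_val
    for _ in range(max_retries + 1):
        A, lo, hi, vlb, vub, integ, c, idx = _assemble_optknock(net, spec, M_cur)
        options: dict = {"mip_rel_gap": 1e-9, "presolve": True}
        if time_limit is not None:
            options["time_limit"] = time_limit
        res = scipy_milp(
            c=c,
            constraints=LinearConstraint(A, lo, hi),
            integrality=integ,
            bounds=Bounds(vlb, vub),
            options=options,
        )
        if res.status == 2 or res.x is None:
            raise RuntimeError(f"OptKnock MILP ended with status {res.status}")
        x = np.asarray(res.x, float)
        M = net.n_reactions
        duals = np.abs(
            np.concatenate([x[idx["p"] : idx["p"] + M], x[idx["q"] : idx["q"] + M],
                            x[idx["e"] : idx["e"] + M], x[idx["f"] : idx["f"] + M]])
        )
        if duals.max(initial=0.0) <= (1 - 1e-4) * M_cur:
            break
        M_cur *= 10.0
    y = x[idx["y"] : idx["y"] + M]
    knockouts = frozenset(
        r for j, r in enumerate(net.reaction_ids) if round(y[j]) == 0
    )
    v = x[idx["v"] : idx["v"] + M]
    moma = solve_moma(net, w, knockouts, spec, exclude_target=True)
    return BaselineResult(
        knockouts=knockouts,
        design_target=float(v[net.target_idx]),
        design_biomass=float(v[net.biomass_idx]),
        moma=moma,
        status="optimal" if res.status == 0 else "limit",
    )


def compare_strategies(
    net: MetabolicNetwork,
    spec: ProblemSpec,
    K_range,
    *,
    momaknock_config=None,
) -> pd.DataFrame:
    """Side-by-side MOMA-inner vs growth-inner designs for each budget K.

    Columns mirror the standard comparison tables: design-phase fluxes, the
    MOMA re-evaluation, and the L2 distance ||v - w||_2 of each mutant's
    MOMA flux from the wild type.
    """
    from momaknock.adaptive import SolverConfig, run_momaknock

    w = solve_fba(net, spec)
    rows = []
    for K in K_range:
        spec_k = ProblemSpec(spec.v_glc_uptake, spec.v_biom_target, int(K))
        mk = run_momaknock(net, spec_k, momaknock_config or SolverConfig(), w=w)
        ok = run_optknock(net, spec_k, w=w)
        flags = {"momaknock": [], "optknock": []}
        if ok.moma.feasible and mk.moma.feasible:
            if mk.moma.target_flux < ok.moma.target_flux - 1e-6:
                flags["momaknock"].append("target_below_baseline")
            if mk.moma.l2_distance > ok.moma.l2_distance + 1e-6:
                flags["momaknock"].append("l2_above_baseline")
        if abs(ok.design_target) <= 1e-6:
            flags["optknock"].append("nonproductive_design")
        if not ok.moma.feasible:
            flags["optknock"].append("lethal_under_moma")
        for method, kos, d_tgt, d_biom, rep in (
            ("momaknock", mk.knockouts, mk.outer_objective,
             mk.moma.biomass_flux if mk.moma.feasible else np.nan, mk.moma),
            ("optknock", ok.knockouts, ok.design_target, ok.design_biomass, ok.moma),
        ):
            rows.append(
                {
                    "K": int(K),
                    "method": method,
                    "knockouts": ",".join(sorted(kos)),
                    "design_target": d_tgt,
                    "design_biomass": d_biom,
                    "moma_status": rep.status,
                    "moma_target": rep.target_flux,
                    "moma_biomass": rep.biomass_flux,
                    "l2_distance": rep.l2_distance,
                    "flag": ";".join(flags[method]),
                }
            )
    return pd.DataFrame(rows)
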