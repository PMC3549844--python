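"""Single-level MILP reformulation of the bi-level knockout problem.

For a fixed piecewise grid, the inner MOMA problem becomes an LP in the
convex-combination variables beta.  Strong LP duality lets the bi-level
program collapse into one MILP containing, side by side:

* the linearized inner *primal* feasibility block over (beta, y) — convexity
  rows, stoichiometry in beta-space, the fixed glucose uptake, the biomass
  floor, and knockout-gated bound rows;
* the inner *dual* feasibility block over (a, b, c, d, mu_glc, mu_biom);
* the strong-duality equality tying the primal cost to the dual objective,
  with the bilinear dual-bound terms c_j*y_j and d_j*y_j replaced by e_j and
  f_j through big-M rows;
* the knockout budget and binary domains, and the outer objective
  max sum_t v_target^t beta_target,t.

Sign conventions are derived mechanically from the primal block: c_j >= 0 is
the dual of the lower-bound row (sum_t v_jt beta_jt >= lb_j y_j) and
d_j >= 0 of the upper-bound row, so the dual objective carries
+ lb_j e_j - ub_j f_j.  The derivation is gated by a numerical fixed-y
primal-vs-dual LP equality test in the suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint
from scipy.optimize import milp as scipy_milp

from momaknock._lp import solve_lp
from momaknock.network import MetabolicNetwork, ProblemSpec
from momaknock.pwl import PiecewiseGrid, cost_coefficients

__all__ = [
    "BilevelModel",
    "MILPSolution",
    "assemble",
    "solve_milp",
    "solve_with_bigm_retry",
    "default_big_m",
    "linearized_inner_lp",
    "linearized_inner_dual_lp",
    "variable_count",
    "constraint_count",
]

#: relative margin for the big-M audit: flag values within 1e-4*M of a bound
BIGM_AUDIT_REL = 1e-4


# ---------------------------------------------------------------------------
# layout and shared beta-space matrices
# ---------------------------------------------------------------------------


@dataclass
class _Layout:
    """Column layout of the MILP variable vector."""

    B: int  # total endpoints
    M: int  # reactions
    N: int  # metabolites
    beta_slices: dict[str, slice]

    @property
    def n(self) -> int:
        return self.B + 6 * self.M + self.N + 2

    def y(self, j: int) -> int:
        return self.B + j

    def a(self, j: int) -> int:
        return self.B + self.M + j

    def b(self, i: int) -> int:
        return self.B + 2 * self.M + i

    def c(self, j: int) -> int:
        return self.B + 2 * self.M + self.N + j

    def d(self, j: int) -> int:
        return self.B + 3 * self.M + self.N + j

    @property
    def mu_glc(self) -> int:
        return self.B + 4 * self.M + self.N

    @property
    def mu_biom(self) -> int:
        return self.B + 4 * self.M + self.N + 1

    def e(self, j: int) -> int:
        return self.B + 4 * self.M + self.N + 2 + j

    def f(self, j: int) -> int:
        return self.B + 5 * self.M + self.N + 2 + j


def _beta_matrices(net: MetabolicNetwork, grid: PiecewiseGrid):
    """Shared matrices over the beta columns.

    conv  (M x B): row j sums beta_j.
    stoich(N x B): column (j,t) carries S[:, j] * v_jt  (stoichiometry of the
                   reconstructed flux).
    flux  (M x B): row j reconstructs v_j = sum_t v_jt beta_jt.
    """
    M, N = net.n_reactions, net.n_metabolites
    sizes = [grid.n_endpoints(r) for r in net.reaction_ids]
    B = sum(sizes)
    offs = np.concatenate([[0], np.cumsum(sizes)])
    slices = {r: slice(offs[j], offs[j + 1]) for j, r in enumerate(net.reaction_ids)}

    conv_rows, conv_cols = [], []
    flux_vals, flux_rows, flux_cols = [], [], []
    st_rows, st_cols, st_vals = [], [], []
    S = net.S.tocsc()
    for j, rid in enumerate(net.reaction_ids):
        pts = grid[rid]
        cols = np.arange(offs[j], offs[j + 1])
        conv_rows.extend([j] * len(cols))
        conv_cols.extend(cols)
        flux_rows.extend([j] * len(cols))
        flux_cols.extend(cols)
        flux_vals.extend(pts)
        col = S.getcol(j).tocoo()
        for i, s_ij in zip(col.row, col.data):
            st_rows.extend([i] * len(cols))
            st_cols.extend(cols)
            st_vals.extend(s_ij * pts)
    conv = sp.csr_matrix((np.ones(len(conv_rows)), (conv_rows, conv_cols)), shape=(M, B))
    flux = sp.csr_matrix((flux_vals, (flux_rows, flux_cols)), shape=(M, B))
    stoich = sp.csr_matrix((st_vals, (st_rows, st_cols)), shape=(N, B))
    layout = _Layout(B=B, M=M, N=N, beta_slices=slices)
    return layout, conv, stoich, flux


def _cost_vector(net, grid, w) -> np.ndarray:
    """Concatenated linearized cost coefficients q_jt, zero for the target."""
    coeffs = cost_coefficients(grid, w)
    out = []
    for rid in net.reaction_ids:
        q = coeffs[rid]
        if rid == net.target_rxn:
            q = np.zeros_like(q)
        out.append(q)
    return np.concatenate(out)


def variable_count(net: MetabolicNetwork, grid: PiecewiseGrid) -> int:
    """Closed-form MILP variable count: sum_j T_j + 6M + N + 2."""
    B = sum(grid.n_endpoints(r) for r in net.reaction_ids)
    return B + 6 * net.n_reactions + net.n_metabolites + 2


def constraint_count(net: MetabolicNetwork, grid: PiecewiseGrid) -> int:
    """Closed-form MILP row count: primal (3M + N + 3) + dual (sum_j T_j)
    + strong duality (1) + big-M (8M)."""
    B = sum(grid.n_endpoints(r) for r in net.reaction_ids)
    M, N = net.n_reactions, net.n_metabolites
    return (M + N + 2 + 2 * M + 1) + B + 1 + 8 * M


# ---------------------------------------------------------------------------
# constraint blocks
# ---------------------------------------------------------------------------


def _expand(A_part: sp.spmatrix, col_offset: int, n: int) -> sp.csr_matrix:
    """Place a block at the given column offset in an all-zero n-column row set."""
    A_part = sp.coo_matrix(A_part)
    return sp.csr_matrix(
        (A_part.data, (A_part.row, A_part.col + col_offset)), shape=(A_part.shape[0], n)
    )


def build_primal_block(net, grid, spec, layout, conv, stoich, flux):
    """Linearized inner primal feasibility over (beta, y) + knockout budget."""
    n = layout.n
    M = layout.M
    rows, lo, hi = [], [], []
    # convexity: sum_t beta_jt = 1
    rows.append(_expand(conv, 0, n))
    lo.append(np.ones(M))
    hi.append(np.ones(M))
    # stoichiometry: S v(beta) = 0
    rows.append(_expand(stoich, 0, n))
    lo.append(np.zeros(layout.N))
    hi.append(np.zeros(layout.N))
    # fixed glucose uptake
    rows.append(_expand(flux[net.glucose_idx], 0, n))
    lo.append([spec.v_glc_uptake])
    hi.append([spec.v_glc_uptake])
    # biomass floor
    rows.append(_expand(flux[net.biomass_idx], 0, n))
    lo.append([spec.v_biom_target])
    hi.append([np.inf])
    # gated bounds: lb_j y_j <= v_j(beta) <= ub_j y_j
    ycols = np.array([layout.y(j) for j in range(M)])
    gate_ub = _expand(flux, 0, n) - sp.csr_matrix(
        (net.ub, (np.arange(M), ycols)), shape=(M, n)
    )
    rows.append(gate_ub)
    lo.append(np.full(M, -np.inf))
    hi.append(np.zeros(M))
    gate_lb = _expand(flux, 0, n) - sp.csr_matrix(
        (net.lb, (np.arange(M), ycols)), shape=(M, n)
    )
    rows.append(gate_lb)
    lo.append(np.zeros(M))
    hi.append(np.full(M, np.inf))
    # budget: sum over candidates of (1 - y_j) <= K
    cand_idx = [net.rxn_idx(r) for r in sorted(net.knockout_candidates)]
    budget = sp.csr_matrix(
        (np.ones(len(cand_idx)), (np.zeros(len(cand_idx), int), [layout.y(j) for j in cand_idx])),
        shape=(1, n),
    )
    rows.append(budget)
    lo.append([len(cand_idx) - spec.K])
    hi.append([np.inf])
    return sp.vstack(rows, format="csr"), np.concatenate([np.atleast_1d(v) for v in lo]).astype(float), np.concatenate(
        [np.atleast_1d(v) for v in hi]
    ).astype(float)


def build_dual_block(net, grid, w, layout, conv, stoich, flux):
    """Inner-dual feasibility: one row per (j, t),
    a_j + sum_i S_ij v_jt b_i + v_jt c_j - v_jt d_j
        (+ v_jt mu_glc on glucose rows, + v_jt mu_biom on biomass rows)
    <= v_jt^2 - 2 w_j v_jt   (0 on target rows).
    """
    n = layout.n
    B = layout.B
    blocks = [
        _expand(conv.T, layout.a(0), n),
        _expand(stoich.T, layout.b(0), n),
        _expand(flux.T, layout.c(0), n),
        _expand(-flux.T, layout.d(0), n),
    ]
    fluxT = flux.T.tocsc()
    glc_col = fluxT.getcol(net.glucose_idx)
    biom_col = fluxT.getcol(net.biomass_idx)
    blocks.append(_expand(glc_col, layout.mu_glc, n))
    blocks.append(_expand(biom_col, layout.mu_biom, n))
    A = sum(blocks[1:], blocks[0])
    q = _cost_vector(net, grid, w)
    return A.tocsr(), np.full(B, -np.inf), q


def build_duality_row(net, grid, w, spec, layout, duality_slack: bool = True):
    """Strong-duality row tying the linearized primal cost to the dual
    objective, with e_j, f_j standing in for c_j y_j and d_j y_j.

    With ``duality_slack`` (default) the equality is relaxed by the
    per-endpoint chord-error budgets sigma_jt:

        sum_jt (q_jt - sigma_jt) beta_jt  <=  dual objective.

    Because the chord overestimates the true quadratic by at most sigma
    within each segment, every *exact* inner optimum of every knockout
    pattern remains feasible, so the MILP optimum is a valid upper bound on
    the bi-level optimum — the property the adaptive refinement needs to
    certify global optimality.  The budget vanishes as segments shrink.
    ``duality_slack=False`` keeps the plain equality (exact only when the
    relevant inner optima lie on grid endpoints).
    """
    n = layout.n
    q = _cost_vector(net, grid, w)
    if duality_slack:
        from momaknock.pwl import slack_coefficients

        sig = slack_coefficients(grid)
        sigma = np.concatenate(
            [np.zeros(grid.n_endpoints(r)) if r == net.target_rxn else sig[r]
             for r in net.reaction_ids]
        )
        q = q - sigma
        lo, hi = np.array([-np.inf]), np.zeros(1)
    else:
        lo, hi = np.zeros(1), np.zeros(1)
    row = sp.lil_matrix((1, n))
    row[0, : layout.B] = q
    for j in range(layout.M):
        row[0, layout.a(j)] = -1.0
    row[0, layout.mu_glc] = -spec.v_glc_uptake
    row[0, layout.mu_biom] = -spec.v_biom_target
    for j in range(layout.M):
        row[0, layout.e(j)] = -net.lb[j]
        row[0, layout.f(j)] = net.ub[j]
    return sp.csr_matrix(row), lo, hi


def build_bigM_block(layout, M_val: float):
    """Exact product linearization e_j = c_j y_j, f_j = d_j y_j for
    c_j, d_j in [0, M]:  -M y <= e <= M y  and  c - M(1-y) <= e <= c + M(1-y)."""
    n = layout.n
    rows, lo, hi = [], [], []
    for var, prod in ((layout.c, layout.e), (layout.d, layout.f)):
        for j in range(layout.M):
            p, v, y = prod(j), var(j), layout.y(j)
            r = sp.lil_matrix((4, n))
            # e - M y <= 0
            r[0, p] = 1.0
            r[0, y] = -M_val
            # e + M y >= 0
            r[1, p] = 1.0
            r[1, y] = M_val
            # e - c + M y <= M
            r[2, p] = 1.0
            r[2, v] = -1.0
            r[2, y] = M_val
            # e - c - M y >= -M
            r[3, p] = 1.0
            r[3, v] = -1.0
            r[3, y] = -M_val
            rows.append(sp.csr_matrix(r))
            lo.extend([-np.inf, 0.0, -np.inf, -M_val])
            hi.extend([0.0, np.inf, M_val, np.inf])
    return sp.vstack(rows, format="csr"), np.array(lo), np.array(hi)


def default_big_m(net: MetabolicNetwork, grid: PiecewiseGrid, w: pd.Series) -> float:
    """Big-M sized from the flux-bound and linearized-cost magnitudes."""
    q = _cost_vector(net, grid, w)
    bound_scale = max(np.max(np.abs(net.lb)), np.max(np.abs(net.ub)), 1.0)
    return 10.0 * max(1.0, float(np.abs(q).max()), bound_scale)


# ---------------------------------------------------------------------------
# assembled model
# ---------------------------------------------------------------------------


@dataclass
class BilevelModel:
    net: MetabolicNetwork
    grid: PiecewiseGrid
    spec: ProblemSpec
    w: pd.Series
    layout: _Layout
    A: sp.csr_matrix
    row_lb: np.ndarray
    row_ub: np.ndarray
    var_lb: np.ndarray
    var_ub: np.ndarray
    integrality: np.ndarray
    c: np.ndarray  # minimize c'x == maximize target flux
    M_val: float
    row_groups: dict[str, slice] = field(default_factory=dict)

    @property
    def n_variables(self) -> int:
        return self.layout.n

    @property
    def n_constraints(self) -> int:
        return self.A.shape[0]


def assemble(
    net: MetabolicNetwork,
    w: pd.Series,
    grid: PiecewiseGrid,
    spec: ProblemSpec,
    M_val: float | None = None,
    *,
    duality_slack: bool = True,
) -> BilevelModel:
    """Build the full single-level MILP for one piecewise grid."""
    layout, conv, stoich, flux = _beta_matrices(net, grid)
    if M_val is None:
        M_val = default_big_m(net, grid, w)

    Ap, lop, hip = build_primal_block(net, grid, spec, layout, conv, stoich, flux)
    Ad, lod, hid = build_dual_block(net, grid, w, layout, conv, stoich, flux)
    Asd, losd, hisd = build_duality_row(net, grid, w, spec, layout, duality_slack)
    Am, lom, him = build_bigM_block(layout, M_val)

    A = sp.vstack([Ap, Ad, Asd, Am], format="csr")
    row_lb = np.concatenate([lop, lod, losd, lom])
    row_ub = np.concatenate([hip, hid, hisd, him])
    groups = {
        "primal": slice(0, Ap.shape[0]),
        "dual": slice(Ap.shape[0], Ap.shape[0] + Ad.shape[0]),
        "duality": slice(Ap.shape[0] + Ad.shape[0], Ap.shape[0] + Ad.shape[0] + 1),
        "bigM": slice(Ap.shape[0] + Ad.shape[0] + 1, A.shape[0]),
    }

    n = layout.n
    var_lb = np.full(n, -np.inf)
    var_ub = np.full(n, np.inf)
    var_lb[: layout.B] = 0.0
    var_ub[: layout.B] = 1.0
    integrality = np.zeros(n)
    cand = net.knockout_candidates
    for j, rid in enumerate(net.reaction_ids):
        yi = layout.y(j)
        if rid in cand:
            var_lb[yi], var_ub[yi] = 0.0, 1.0
            integrality[yi] = 1
        else:
            var_lb[yi], var_ub[yi] = 1.0, 1.0
    for j in range(layout.M):
        var_lb[layout.c(j)] = 0.0
        var_lb[layout.d(j)] = 0.0
    var_lb[layout.mu_biom] = 0.0

    c = np.zeros(n)
    tgt = net.target_rxn
    c[layout.beta_slices[tgt]] = -grid[tgt]  # maximize reconstructed target flux

    return BilevelModel(
        net=net,
        grid=grid,
        spec=spec,
        w=w,
        layout=layout,
        A=A,
        row_lb=row_lb,
        row_ub=row_ub,
        var_lb=var_lb,
        var_ub=var_ub,
        integrality=integrality,
        c=c,
        M_val=M_val,
        row_groups=groups,
    )


# ---------------------------------------------------------------------------
# solve + audits
# ---------------------------------------------------------------------------


@dataclass
class MILPSolution:
    status: str  # "optimal" | "infeasible" | "limit" | "failed"
    outer_objective: float = np.nan
    y: dict[str, int] = field(default_factory=dict)
    knockouts: frozenset[str] = frozenset()
    beta: dict[str, np.ndarray] = field(default_factory=dict)
    duals: dict[str, np.ndarray] = field(default_factory=dict)
    x: np.ndarray | None = None
    primal_residual: float = np.nan
    duality_residual: float = np.nan
    bigm_ok: bool = True
    M_val: float = np.nan

    @property
    def feasible(self) -> bool:
        return self.status in ("optimal", "limit")


def solve_milp(
    model: BilevelModel,
    lower_bound: float | None = None,
    *,
    seed: int = 0,
    time_limit: float | None = None,
    mip_gap: float = 1e-9,
    nogood_sets=(),
    fixed_y: frozenset[str] | None = None,
) -> MILPSolution:
    """Solve the assembled MILP with HiGHS (deterministic; ``seed`` is kept
    for interface stability).

    A finite ``lower_bound`` on the outer objective is added as a valid cut
    (warm-start bound).  ``nogood_sets`` are knockout sets to exclude from
    the binary search space; ``fixed_y`` freezes the binaries to one given
    knockout set (restriction solve).
    """
    A, row_lb, row_ub = model.A, model.row_lb, model.row_ub
    if lower_bound is not None and np.isfinite(lower_bound):
        cut = sp.csr_matrix(-model.c)  # target flux row
        slack = 1e-7 * (1.0 + abs(lower_bound))
        A = sp.vstack([A, cut], format="csr")
        row_lb = np.append(row_lb, lower_bound - slack)
        row_ub = np.append(row_ub, np.inf)
    if nogood_sets:
        net, lay = model.net, model.layout
        cand = sorted(model.net.knockout_candidates)
        rows, los = [], []
        for s in nogood_sets:
            # exclude exactly this knockout pattern over the candidates:
            # sum_{j in s} y_j + sum_{j in cand \ s} (1 - y_j) >= 1
            cols = [lay.y(net.rxn_idx(r)) for r in cand]
            vals = [1.0 if r in s else -1.0 for r in cand]
            rows.append(
                sp.csr_matrix((vals, (np.zeros(len(cols), int), cols)), shape=(1, lay.n))
            )
            los.append(1.0 - sum(1 for r in cand if r not in s))
        A = sp.vstack([A] + rows, format="csr")
        row_lb = np.concatenate([row_lb, los])
        row_ub = np.concatenate([row_ub, np.full(len(rows), np.inf)])
    var_lb, var_ub = model.var_lb, model.var_ub
    integrality = model.integrality
    if fixed_y is not None:
        var_lb = var_lb.copy()
        var_ub = var_ub.copy()
        for j, rid in enumerate(model.net.reaction_ids):
            val = 0.0 if rid in fixed_y else 1.0
            var_lb[model.layout.y(j)] = val
            var_ub[model.layout.y(j)] = val
        # all binaries pinned: the restriction is a plain LP; HiGHS's MIP
        # presolve can misjudge the degenerate strong-duality face, the LP
        # simplex does not
        integrality = np.zeros(model.layout.n)
    # presolve misjudges the degenerate strong-duality face of the pinned
    # (continuous) restriction problem; the plain simplex handles it
    options: dict = {"mip_rel_gap": mip_gap, "presolve": fixed_y is None}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = scipy_milp(
        c=model.c,
        constraints=LinearConstraint(A, row_lb, row_ub),
        integrality=integrality,
        bounds=Bounds(var_lb, var_ub),
        options=options,
    )
    if res.status == 2:
        return MILPSolution(status="infeasible", M_val=model.M_val)
    if res.x is None:
        return MILPSolution(status="failed", M_val=model.M_val)
    status = "optimal" if res.status == 0 else "limit"
    return _extract(model, np.asarray(res.x, float), status)


def _extract(model: BilevelModel, x: np.ndarray, status: str) -> MILPSolution:
    lay = model.layout
    net = model.net
    y = {}
    for j, rid in enumerate(net.reaction_ids):
        y[rid] = int(round(x[lay.y(j)]))
    knockouts = frozenset(r for r, v in y.items() if v == 0)
    beta = {r: x[lay.beta_slices[r]].copy() for r in net.reaction_ids}
    M = lay.M
    duals = {
        "a": x[lay.a(0) : lay.a(0) + M].copy(),
        "b": x[lay.b(0) : lay.b(0) + lay.N].copy(),
        "c": x[lay.c(0) : lay.c(0) + M].copy(),
        "d": x[lay.d(0) : lay.d(0) + M].copy(),
        "mu_glc": float(x[lay.mu_glc]),
        "mu_biom": float(x[lay.mu_biom]),
        "e": x[lay.e(0) : lay.e(0) + M].copy(),
        "f": x[lay.f(0) : lay.f(0) + M].copy(),
    }
    # residual audits
    g = model.row_groups
    Ax = model.A @ x
    prim = slice(g["primal"].start, g["primal"].stop)
    viol = np.maximum(model.row_lb - Ax, Ax - model.row_ub)
    viol[~np.isfinite(viol)] = -np.inf
    primal_residual = float(np.max(viol[prim], initial=-np.inf))
    k = g["duality"].start
    sd = float(
        max(
            Ax[k] - model.row_ub[k] if np.isfinite(model.row_ub[k]) else -np.inf,
            model.row_lb[k] - Ax[k] if np.isfinite(model.row_lb[k]) else -np.inf,
            0.0,
        )
    )
    y_arr = np.array([y[r] for r in net.reaction_ids])
    bigm_ok = _bigm_audit(duals, y_arr, model.M_val)
    return MILPSolution(
        status=status,
        outer_objective=float(-model.c @ x),
        y=y,
        knockouts=knockouts,
        beta=beta,
        duals=duals,
        x=x,
        primal_residual=max(primal_residual, 0.0),
        duality_residual=sd,
        bigm_ok=bigm_ok,
        M_val=model.M_val,
    )


def _bigm_audit(duals: dict, y: np.ndarray, M_val: float) -> bool:
    """The product rows are exact iff c_j, d_j stay below M on *active*
    (y=1) reactions; for knocked-out reactions the bound duals are free
    slack (e_j = f_j = 0 regardless), so a bound-touching value there is
    degeneracy, not a big-M failure."""
    margin = (1.0 - BIGM_AUDIT_REL) * M_val
    active = y >= 0.5
    for k in ("c", "d"):
        if np.any(np.abs(duals[k][active]) > margin):
            return False
    for k in ("e", "f"):
        if np.any(np.abs(duals[k]) > margin):
            return False
    return True


def solve_with_bigm_retry(
    net: MetabolicNetwork,
    w: pd.Series,
    grid: PiecewiseGrid,
    spec: ProblemSpec,
    *,
    M_val: float | None = None,
    lower_bound: float | None = None,
    seed: int = 0,
    time_limit: float | None = None,
    max_retries: int = 3,
    duality_slack: bool = True,
    nogood_sets=(),
    fixed_y: frozenset[str] | None = None,
) -> tuple[MILPSolution, BilevelModel]:
    """Assemble + solve, escalating M by x10 whenever the post-solve audit
    finds a dual/product variable pressed against a big-M bound."""
    M_cur = M_val if M_val is not None else default_big_m(net, grid, w)
    for _ in range(max_retries + 1):
        model = assemble(net, w, grid, spec, M_val=M_cur, duality_slack=duality_slack)
        sol = solve_milp(
            model, lower_bound, seed=seed, time_limit=time_limit,
            nogood_sets=nogood_sets, fixed_y=fixed_y,
        )
        if not sol.feasible or sol.bigm_ok:
            return sol, model
        M_cur *= 10.0
    return sol, model


# ---------------------------------------------------------------------------
# fixed-y linearized LPs (used for warm bounds and the duality gate)
# ---------------------------------------------------------------------------


def linearized_inner_lp(
    net: MetabolicNetwork,
    w: pd.Series,
    grid: PiecewiseGrid,
    y: dict[str, int],
    spec: ProblemSpec,
):
    """Solve the linearized inner *primal* LP over beta for fixed knockouts.

    Returns (beta dict, optimal linearized cost) or (None, nan) if infeasible.
    """
    layout, conv, stoich, flux = _beta_matrices(net, grid)
    B = layout.B
    yv = np.array([float(y[r]) for r in net.reaction_ids])
    rows = [conv, stoich, flux[net.glucose_idx], flux[net.biomass_idx], flux, flux]
    lo = np.concatenate(
        [
            np.ones(layout.M),
            np.zeros(layout.N),
            [spec.v_glc_uptake, spec.v_biom_target],
            np.full(layout.M, -np.inf),
            net.lb * yv,
        ]
    )
    hi = np.concatenate(
        [
            np.ones(layout.M),
            np.zeros(layout.N),
            [spec.v_glc_uptake, np.inf],
            net.ub * yv,
            np.full(layout.M, np.inf),
        ]
    )
    q = _cost_vector(net, grid, w)
    res = solve_lp(q, sp.vstack(rows), lo, hi, np.zeros(B), np.ones(B))
    if res.status != "optimal":
        return None, np.nan
    beta = {r: res.x[layout.beta_slices[r]].copy() for r in net.reaction_ids}
    return beta, float(res.fun)


def linearized_inner_dual_lp(
    net: MetabolicNetwork,
    w: pd.Series,
    grid: PiecewiseGrid,
    y: dict[str, int],
    spec: ProblemSpec,
):
    """Solve the inner *dual* LP for fixed knockouts; returns its optimum.

    max  sum_j a_j + uptake*mu_glc + biom_floor*mu_biom
         + sum_j lb_j y_j c_j - sum_j ub_j y_j d_j
    subject to the dual feasibility rows.  Equals the primal LP optimum at
    optimality (strong duality) — the correctness gate for the derivation.
    """
    layout, conv, stoich, flux = _beta_matrices(net, grid)
    # dual variable vector: [a (M), b (N), c (M), d (M), mu_glc, mu_biom]
    M, N = layout.M, layout.N
    nd = 3 * M + N + 2
    fluxT = flux.T.tocsc()
    A = sp.hstack(
        [
            conv.T,
            stoich.T,
            fluxT,
            -fluxT,
            fluxT.getcol(net.glucose_idx),
            fluxT.getcol(net.biomass_idx),
        ],
        format="csr",
    )
    q = _cost_vector(net, grid, w)
    yv = np.array([float(y[r]) for r in net.reaction_ids])
    obj = np.concatenate(
        [
            np.ones(M),
            np.zeros(N),
            net.lb * yv,
            -net.ub * yv,
            [spec.v_glc_uptake, spec.v_biom_target],
        ]
    )
    lo_var = np.concatenate(
        [np.full(M + N, -np.inf), np.zeros(2 * M), [-np.inf, 0.0]]
    )
    hi_var = np.full(nd, np.inf)
    res = solve_lp(-obj, A, np.full(layout.B, -np.inf), q, lo_var, hi_var)
    if res.status != "optimal":
        return None, np.nan
    return res.x, float(-res.fun)
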