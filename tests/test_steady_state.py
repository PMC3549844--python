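"""Phenotype layer: FBA against an independent GLPK route, MOMA against an
independent convex-programming route, and the stated invariants."""

import numpy as np
import pytest
from scipy.optimize import Bounds, LinearConstraint, minimize

from momaknock import (
    InfeasibleModelError,
    generate_toy_network,
    solve_fba,
    solve_moma,
    theoretical_max,
)
from momaknock.network import ProblemSpec
from tests.conftest import build_cobra_model


def _moma_oracle(net, w, knockouts, spec, exclude_target):
    """Independent MOMA solve via scipy trust-constr (no OSQP involved)."""
    lb, ub = net.lb.copy(), net.ub.copy()
    for rid in knockouts:
        j = net.rxn_idx(rid)
        lb[j] = ub[j] = 0.0
    g, b = net.glucose_idx, net.biomass_idx
    lb[g] = ub[g] = spec.v_glc_uptake
    lb[b] = max(lb[b], spec.v_biom_target)
    wt = w.to_numpy()
    weights = np.ones(net.n_reactions)
    if exclude_target:
        weights[net.target_idx] = 0.0
    res = minimize(
        lambda v: float(np.sum(weights * (v - wt) ** 2)),
        np.clip(wt, lb, ub),
        jac=lambda v: 2.0 * weights * (v - wt),
        method="trust-constr",
        constraints=[LinearConstraint(net.S.toarray(), 0.0, 0.0)],
        bounds=Bounds(lb, ub),
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 5000},
    )
    return float(res.fun)


class TestFBA:
    def test_biomass_matches_glpk_oracle(self, toy_net, spec, wild_type):
        model = build_cobra_model(toy_net, spec)
        model.objective = toy_net.biomass_rxn
        ref = model.optimize().objective_value
        assert wild_type[toy_net.biomass_rxn] == pytest.approx(ref, rel=1e-7)

    def test_minimum_norm_reference_is_biomass_optimal(self, toy_net, spec, wild_type):
        plain = solve_fba(toy_net, spec, minimize_norm=False)
        assert wild_type[toy_net.biomass_rxn] == pytest.approx(
            plain[toy_net.biomass_rxn], rel=1e-8
        )
        assert np.linalg.norm(wild_type) <= np.linalg.norm(plain) + 1e-7

    def test_blocked_biomass_raises(self, toy_net, spec):
        ub = toy_net.ub.copy()
        ub[toy_net.biomass_idx] = 0.0
        blocked = toy_net.with_bounds(toy_net.lb, ub)
        with pytest.raises(InfeasibleModelError):
            solve_fba(blocked, spec)

    def test_mass_balance_residual(self, toy_net, wild_type):
        v = wild_type.to_numpy()
        assert np.abs(toy_net.S @ v).max() <= 1e-6 * max(1.0, np.abs(v).max())


class TestTheoreticalMax:
    def test_matches_glpk_oracle(self, toy_net, spec):
        model = build_cobra_model(toy_net, spec)
        model.objective = toy_net.target_rxn
        ref = model.optimize().objective_value
        got = theoretical_max(toy_net, toy_net.target_rxn, spec)
        assert got == pytest.approx(ref, rel=1e-7)

    def test_zero_when_target_closed(self, toy_net, spec):
        ub = toy_net.ub.copy()
        ub[toy_net.target_idx] = 0.0
        closed = toy_net.with_bounds(toy_net.lb, ub)
        assert theoretical_max(closed, closed.target_rxn, spec) == pytest.approx(
            0.0, abs=1e-9
        )


class TestMOMA:
    def test_identity_with_empty_knockouts(self, toy_net, spec, wild_type):
        rep = solve_moma(toy_net, wild_type, frozenset(), spec, exclude_target=False)
        assert rep.feasible
        assert rep.moma_objective == pytest.approx(0.0, abs=1e-8)
        assert np.abs(rep.flux - wild_type).max() < 1e-8

    @pytest.mark.parametrize("exclude_target", [True, False])
    def test_matches_independent_qp(self, toy_net, spec, wild_type, exclude_target):
        kos = frozenset({"R_BD"})
        rep = solve_moma(toy_net, wild_type, kos, spec, exclude_target=exclude_target)
        ref = _moma_oracle(toy_net, wild_type, kos, spec, exclude_target)
        assert rep.moma_objective == pytest.approx(ref, rel=1e-6, abs=1e-6)

    def test_optimum_below_random_feasible_points(self, toy_net, spec, wild_type):
        """The QP optimum never exceeds the objective at random feasible
        fluxes (constructed by perturbing within the null space)."""
        kos = frozenset({"R_AB"})
        rep = solve_moma(toy_net, wild_type, kos, spec, exclude_target=True)
        assert rep.feasible
        rng = np.random.default_rng(0)
        wt = wild_type.to_numpy()
        weights = np.ones(toy_net.n_reactions)
        weights[toy_net.target_idx] = 0.0
        # feasible points: convex combinations of the MOMA flux and an FBA
        # vertex of the same knockout polytope
        lb, ub = toy_net.lb.copy(), toy_net.ub.copy()
        j = toy_net.rxn_idx("R_AB")
        lb[j] = ub[j] = 0.0
        alt = solve_fba(toy_net.with_bounds(lb, ub), spec, minimize_norm=False)
        for _ in range(10):
            lam = rng.uniform(0, 1)
            v = lam * rep.flux.to_numpy() + (1 - lam) * alt.to_numpy()
            obj = float(np.sum(weights * (v - wt) ** 2))
            assert obj >= rep.moma_objective - 1e-7

    def test_lethal_design_reports_infeasible(self, spec):
        net = generate_toy_network(4, seed=0)
        # sever every route out of the substrate node: no steady state can
        # absorb the fixed uptake
        rep = solve_moma(
            net,
            solve_fba(net, spec),
            frozenset({"R_AB", "R_AC"}),
            spec,
            exclude_target=True,
        )
        assert rep.status == "infeasible"
        assert not rep.feasible

    def test_optimistic_target_never_below_nonoptimistic(self, toy_net, spec, wild_type):
        rep = solve_moma(toy_net, wild_type, frozenset(), spec, exclude_target=True)
        assert rep.feasible
        assert rep.target_flux >= wild_type[toy_net.target_rxn] - 1e-7
        # non-target fluxes pinned at the wild type (unique strictly convex optimum)
        others = [r for r in toy_net.reaction_ids if r != toy_net.target_rxn]
        assert np.abs(rep.flux[others] - wild_type[others]).max() < 1e-5

    def test_unknown_knockout_id_raises(self, toy_net, spec, wild_type):
        with pytest.raises(KeyError):
            solve_moma(toy_net, wild_type, frozenset({"NOPE"}), spec)
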