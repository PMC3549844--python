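"""Piecewise-linearization machinery: construction rules, the chordal
overestimate, gap arithmetic and refinement behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from momaknock.pwl import (
    PiecewiseGrid,
    converged,
    cost_coeff,
    gap,
    initial_grid,
    reconstruct,
    refine,
    slack_coefficients,
)


def _grid1(points, rid="R"):
    return PiecewiseGrid(reaction_ids=[rid], points={rid: np.asarray(points, float)})


def _w(value, rid="R"):
    return pd.Series({rid: float(value)})


class TestInitialGrid:
    def test_inserts_zero_and_wildtype(self, toy_net, wild_type):
        # symmetric-bound reaction: 2 segments + 0 + w
        import dataclasses

        net = dataclasses.replace(toy_net)
        lb, ub = net.lb.copy(), net.ub.copy()
        lb[1], ub[1] = -10.0, 10.0
        net = net.with_bounds(lb, ub)
        w = wild_type.copy()
        w[net.reaction_ids[1]] = 3.0
        grid = initial_grid(net, w, k_init=2)
        np.testing.assert_allclose(
            grid[net.reaction_ids[1]], [-10.0, 0.0, 3.0, 10.0]
        )

    def test_single_segment_no_interior_inserts(self, toy_net, wild_type):
        w = wild_type.copy()
        w[:] = 0.0
        net = toy_net.with_bounds(np.zeros(toy_net.n_reactions), np.full(toy_net.n_reactions, 10.0))
        grid = initial_grid(net, w, k_init=1)
        for rid in (r for r in net.reaction_ids):
            np.testing.assert_allclose(grid[rid], [0.0, 10.0])

    def test_bounds_are_first_and_last(self, toy_net, wild_type):
        grid = initial_grid(toy_net, wild_type, k_init=4)
        for j, rid in enumerate(toy_net.reaction_ids):
            pts = grid[rid]
            assert pts[0] == toy_net.lb[j]
            assert pts[-1] == toy_net.ub[j]
            assert np.all(np.diff(pts) > 0)

    def test_k_init_must_be_positive(self, toy_net, wild_type):
        with pytest.raises(ValueError):
            initial_grid(toy_net, wild_type, k_init=0)


class TestCostCoeff:
    @pytest.mark.parametrize(
        "v, w, expected",
        [(3.0, 3.0, -9.0), (0.0, 5.0, 0.0), (2.0, 0.0, 4.0)],
    )
    def test_algebra(self, v, w, expected):
        grid = _grid1([min(v, 0.0) - 1.0, v, max(v, 0.0) + 1.0])
        t = int(np.searchsorted(grid["R"], v))
        assert cost_coeff(grid, _w(w), "R", t) == pytest.approx(expected)


class TestReconstruct:
    def test_concentrated_beta_returns_endpoint(self):
        grid = _grid1([0.0, 2.0, 5.0])
        v = reconstruct(grid, {"R": np.array([0.0, 1.0, 0.0])})
        assert v["R"] == pytest.approx(2.0)

    def test_midpoint(self):
        grid = _grid1([0.0, 2.0])
        v = reconstruct(grid, {"R": np.array([0.5, 0.5])})
        assert v["R"] == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_stays_within_bounds(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.sort(rng.uniform(-10, 10, size=rng.integers(2, 7)))
        pts[0], pts[-1] = -10.0, 10.0
        pts = np.unique(pts)
        grid = _grid1(pts)
        b = rng.dirichlet(np.ones(len(pts)))
        v = reconstruct(grid, {"R": b})["R"]
        assert pts[0] - 1e-12 <= v <= pts[-1] + 1e-12


class TestGap:
    def test_concentrated_beta_zero_gap(self):
        grid = _grid1([0.0, 2.0, 5.0])
        rec = gap(grid, {"R": np.array([0.0, 1.0, 0.0])}, _w(1.0))
        assert rec.delta["R"] == pytest.approx(0.0, abs=1e-12)

    def test_textbook_two_endpoint_value(self):
        # endpoints {0,2}, w=0, beta=(1/2,1/2): chord cost 2, true cost 1
        grid = _grid1([0.0, 2.0])
        rec = gap(grid, {"R": np.array([0.5, 0.5])}, _w(0.0))
        assert rec.delta["R"] == pytest.approx(1.0)
        assert rec.insert_at["R"] == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_chord_overestimates_quadratic(self, seed):
        """sum_t (v_t - w)^2 b_t >= (sum_t v_t b_t - w)^2 for any valid beta
        (Jensen), with the gap matching linearized-minus-true exactly."""
        rng = np.random.default_rng(seed)
        pts = np.unique(np.sort(rng.uniform(-20, 20, size=rng.integers(2, 8))))
        if len(pts) < 2:
            pts = np.array([-1.0, 1.0])
        grid = _grid1(pts)
        b = rng.dirichlet(np.ones(len(pts)))
        w = float(rng.uniform(-15, 15))
        rec = gap(grid, {"R": b}, _w(w))
        v_hat = float(b @ pts)
        lin = float(b @ (pts - w) ** 2)
        assert rec.delta["R"] >= -1e-10
        assert rec.delta["R"] == pytest.approx(lin - (v_hat - w) ** 2, abs=1e-9)

    def test_adjacent_pair_matches_two_point_formula(self):
        rng = np.random.default_rng(7)
        pts = np.array([-3.0, 1.0, 4.0, 9.0])
        grid = _grid1(pts)
        for _ in range(20):
            t = rng.integers(0, 3)
            lam = rng.uniform()
            b = np.zeros(4)
            b[t], b[t + 1] = lam, 1 - lam
            w = rng.uniform(-5, 5)
            rec = gap(grid, {"R": b}, _w(w))
            direct = (
                (pts[t] - w) ** 2 * b[t]
                + (pts[t + 1] - w) ** 2 * b[t + 1]
                - (pts[t] * b[t] + pts[t + 1] * b[t + 1] - w) ** 2
            )
            assert rec.delta["R"] == pytest.approx(direct, abs=1e-10)


class TestRefine:
    def test_inserts_reconstructed_point(self):
        grid = _grid1([0.0, 2.0])
        rec = gap(grid, {"R": np.array([0.5, 0.5])}, _w(0.0))
        new, added = refine(grid, rec, eps=1e-9, theta=0.999)
        assert added == 1
        np.testing.assert_allclose(new["R"], [0.0, 1.0, 2.0])

    def test_converged_reaction_untouched(self):
        grid = _grid1([0.0, 2.0])
        rec = gap(grid, {"R": np.array([1.0, 0.0])}, _w(0.0))
        new, added = refine(grid, rec, eps=1e-9, theta=0.999)
        assert added == 0
        np.testing.assert_allclose(new["R"], [0.0, 2.0])

    def test_repeated_refinement_drives_gap_down(self):
        """Fix a flux value; re-represent it on ever finer grids: the chordal
        gap is non-increasing and tends to zero."""
        grid = _grid1([0.0, 8.0])
        w = _w(1.5)
        v_fix = 3.3
        last = np.inf
        for _ in range(12):
            pts = grid["R"]
            t = int(np.searchsorted(pts, v_fix)) - 1
            lam = (pts[t + 1] - v_fix) / (pts[t + 1] - pts[t])
            b = np.zeros(len(pts))
            b[t], b[t + 1] = lam, 1 - lam
            rec = gap(grid, {"R": b}, w)
            assert rec.delta["R"] <= last + 1e-12
            last = rec.delta["R"]
            grid, _ = refine(grid, rec, eps=1e-14, theta=1 - 1e-12)
        assert last < 1e-3

    def test_never_moves_bound_endpoints(self, toy_net, wild_type):
        grid = initial_grid(toy_net, wild_type, k_init=3)
        beta = {
            rid: np.full(grid.n_endpoints(rid), 1.0 / grid.n_endpoints(rid))
            for rid in toy_net.reaction_ids
        }
        rec = gap(grid, beta, wild_type)
        new, _ = refine(grid, rec, eps=1e-12, theta=0.999)
        for j, rid in enumerate(toy_net.reaction_ids):
            assert new[rid][0] == toy_net.lb[j]
            assert new[rid][-1] == toy_net.ub[j]


class TestConverged:
    def test_all_concentrated_converges(self):
        grid = _grid1([0.0, 1.0, 2.0])
        rec = gap(grid, {"R": np.array([0.0, 1.0, 0.0])}, _w(0.5))
        assert converged(rec, eps=1e-6, theta=0.999)

    def test_large_gap_blocks(self):
        grid = _grid1([0.0, 2.0])
        rec = gap(grid, {"R": np.array([0.5, 0.5])}, _w(0.0))
        assert not converged(rec, eps=0.5, theta=0.4)

    def test_spread_beta_blocks_even_with_small_gap(self):
        grid = _grid1([0.0, 1e-4, 2.0])
        b = np.array([0.5, 0.5, 0.0])
        rec = gap(grid, {"R": b}, _w(0.0))
        assert rec.delta["R"] < 1e-6
        assert not converged(rec, eps=1e-6, theta=0.999)


class TestSlackBudget:
    def test_budget_dominates_chord_error_within_segment(self):
        rng = np.random.default_rng(3)
        pts = np.array([-5.0, -1.0, 2.0, 10.0])
        grid = _grid1(pts)
        sig = slack_coefficients(grid)["R"]
        for _ in range(50):
            t = rng.integers(0, 3)
            lam = rng.uniform()
            v = lam * pts[t] + (1 - lam) * pts[t + 1]
            w = rng.uniform(-8, 8)
            chord = lam * (pts[t] - w) ** 2 + (1 - lam) * (pts[t + 1] - w) ** 2
            err = chord - (v - w) ** 2
            budget = lam * sig[t] + (1 - lam) * sig[t + 1]
            assert err <= budget + 1e-10

    def test_fixed_grid_zero_budget(self):
        grid = _grid1([2.0])
        assert slack_coefficients(grid)["R"].tolist() == [0.0]
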