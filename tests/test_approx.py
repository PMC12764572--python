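"""Piecewise-linear tables, error metrics, and the breakpoint search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from burstnet.approx import (PiecewiseLinear, PiecewiseFit, SearchConfig,
                             cube_table, square_table, exp_table,
                             nmae_curve, nrmse_curve, search_best_fit,
                             eval_piecewise)


class TestFixedTables:
    @pytest.mark.parametrize("name,n", [("cube", 10), ("square", 8),
                                        ("exp", 10)])
    def test_segment_counts(self, tables, name, n):
        assert tables[name].n_segments == n

    @pytest.mark.parametrize("name,x,expected", [
        ("cube", 0.0, 0.0),
        ("cube", 2.0, 6.33 * 2 - 6.03),
        ("cube", -2.0, -(6.33 * 2 - 6.03)),
        ("square", 0.0, 0.0),
        ("exp", 0.0, 0.999),
        ("exp", 40.0, -0.0020 * 40 + 0.1),
    ])
    def test_point_evaluations(self, tables, name, x, expected):
        assert tables[name](x) == pytest.approx(expected, abs=1e-12)

    def test_cube_odd_symmetry(self, tables):
        x = np.linspace(0.01, 2.5, 400)
        np.testing.assert_allclose(tables["cube"](-x), -tables["cube"](x),
                                   atol=1e-12)

    def test_square_even_symmetry(self, tables):
        # holds only after correcting the final breakpoint to 1.21
        x = np.linspace(0.01, 2.5, 400)
        np.testing.assert_allclose(tables["square"](-x), tables["square"](x),
                                   atol=1e-12)

    def test_exp_positive_and_nonincreasing(self, tables):
        # the last segment touches zero exactly at lag 50, and the printed
        # coefficients leave sub-1e-3 upward jumps at segment boundaries
        t = np.linspace(0.0, 50.0, 2000)
        v = tables["exp"](t)
        assert np.all(v[:-1] > 0) and v[-1] == pytest.approx(0.0)
        assert np.all(np.diff(v) <= 1e-3)

    @pytest.mark.parametrize("name", ["cube", "square", "exp"])
    def test_near_continuity_at_breakpoints(self, tables, name):
        # printed tables are continuous to rounding: adjacent segments
        # evaluated at the shared breakpoint differ by < 0.05
        pw = tables[name]
        for i, bp in enumerate(pw.breakpoints):
            left = pw.slopes[i] * bp + pw.intercepts[i]
            right = pw.slopes[i + 1] * bp + pw.intercepts[i + 1]
            assert abs(left - right) < 0.05

    def test_breakpoint_belongs_to_right_segment(self, tables):
        pw = tables["cube"]
        bp = pw.breakpoints[0]
        assert pw.segment_index(bp) == 1
        assert pw.segment_index(bp - 1e-12) == 0

    def test_eval_piecewise_alias(self, tables):
        assert eval_piecewise(tables["cube"], 2.0) == tables["cube"](2.0)

    def test_segments_roundtrip(self, tables, tmp_path):
        pw = tables["square"]
        path = tmp_path / "square.txt"
        pw.to_text(path)
        back = PiecewiseLinear.from_text(path)
        x = np.linspace(-3, 3, 101)
        np.testing.assert_allclose(back(x), pw(x))

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            PiecewiseLinear(np.array([1.0, 0.5]), np.array([1, 1, 1.0]),
                            np.array([0, 0, 0.0]))
        with pytest.raises(ValueError):
            PiecewiseLinear(np.array([0.0]), np.array([1.0]),
                            np.array([0.0]))


class TestErrorMetrics:
    def test_identical_curves_are_zero(self, rng):
        c = rng.random(50) + 0.5
        assert nmae_curve(c, c) == 0.0
        assert nrmse_curve(c, c) == 0.0

    def test_hand_computed_values(self):
        assert nmae_curve([1.0, 2.0], [1.0, 1.0]) == pytest.approx(0.25)
        assert nrmse_curve([2.0, 2.0], [2.0, 0.0]) == pytest.approx(
            np.sqrt(2.0) / 2.0)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            nmae_curve([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            nrmse_curve([0.0, -1.0], [0.0, -1.0])  # max(ref) == 0

    def test_matches_bruteforce_oracle(self, rng):
        # plain-python summation, independent of the vectorized path
        for _ in range(5):
            ref = rng.random(100) + 0.1
            approx = ref + 0.2 * rng.standard_normal(100)
            n, mx = len(ref), max(ref)
            nmae_o = sum(abs(r - a) for r, a in zip(ref, approx)) / (n * mx)
            nrmse_o = (sum((r - a) ** 2 for r, a in zip(ref, approx))
                       / n) ** 0.5 / mx
            assert nmae_curve(ref, approx) == pytest.approx(nmae_o, abs=1e-12)
            assert nrmse_curve(ref, approx) == pytest.approx(nrmse_o,
                                                             abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(shift=st.floats(-5, 5), scale=st.floats(0.1, 3))
    def test_nmae_scale_behaviour(self, shift, scale):
        # adding a constant offset d to the approximation gives |d|/max(ref)
        ref = np.linspace(1.0, 2.0, 11)
        got = nmae_curve(ref, ref + shift)
        assert got == pytest.approx(abs(shift) / 2.0, rel=1e-9)
        # scaling both curves leaves the normalized error invariant
        assert nmae_curve(scale * ref, scale * (ref + shift)) == pytest.approx(
            got, rel=1e-9)


class TestSearch:
    def test_linear_target_is_exact_with_two_points(self):
        cfg = SearchConfig(target_function=lambda x: 3.0 * x - 1.0,
                           domain=(-2, 2), error_tolerance=1e-6,
                           grid_resolution=501, n_restarts=20)
        table, err = search_best_fit(cfg, seed=0)
        assert err < 1e-9
        assert table.n_segments == 1

    def test_square_meets_published_tolerance(self):
        cfg = SearchConfig(target_function=np.square, domain=(-2, 2),
                           error_tolerance=0.015, grid_resolution=2001,
                           n_restarts=150)
        res = PiecewiseFit(cfg).fit(seed=3)
        assert res.converged
        assert res.achieved_error <= 0.015
        assert "converged" in res.summary()

    def test_cube_meets_tolerance(self):
        cfg = SearchConfig(target_function=lambda x: x ** 3, domain=(-2, 2),
                           error_tolerance=0.03, grid_resolution=2001,
                           n_restarts=150)
        _, err = search_best_fit(cfg, seed=5)
        assert err <= 0.03

    def test_more_points_do_not_hurt_on_average(self):
        # achieved error is non-increasing in the point budget in
        # expectation over seeds
        def run(n_max, seed):
            cfg = SearchConfig(target_function=np.square, domain=(-2, 2),
                               n_points_max=n_max, error_tolerance=1e-9,
                               grid_resolution=401, n_restarts=15)
            return PiecewiseFit(cfg).fit(seed).achieved_error

        seeds = range(20)
        small = np.mean([run(3, s) for s in seeds])
        large = np.mean([run(6, s) for s in seeds])
        assert large <= small

    def test_nonconvergence_still_returns_best(self):
        cfg = SearchConfig(target_function=np.square, domain=(-2, 2),
                           n_points_max=2, error_tolerance=1e-9,
                           grid_resolution=401, n_restarts=10)
        res = PiecewiseFit(cfg).fit(seed=0)
        assert not res.converged
        assert np.isfinite(res.achieved_error)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SearchConfig(target_function=np.square, domain=(0, 1),
                         n_points_min=1)
        with pytest.raises(ValueError):
            SearchConfig(target_function=np.square, domain=(0, 1),
                         n_points_max=12)
        with pytest.raises(ValueError):
            SearchConfig(target_function=np.square, domain=(0, 1),
                         error_tolerance=0.0)
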