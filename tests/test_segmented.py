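import numpy as np
import pytest

from vpdpheno.segmented import davies_test, fit_segmented, profile_rss


def grid_oracle(x, y, n_grid=2000):
    """Exhaustive RSS profiling over candidate breakpoints (single
    common intercept), independent of the iterative fitter."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.linspace(x.min() + 1e-9, x.max() - 1e-9, n_grid)
    ones = np.ones(len(x))
    best = (np.inf, grid[0])
    for psi in grid:
        design = np.column_stack([ones, x, np.clip(x - psi, 0.0, None)])
        beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        r = y - design @ beta
        rss = float(r @ r)
        if rss < best[0]:
            best = (rss, psi)
    return best[1], best[0], (x.max() - x.min()) / n_grid


class TestFitSegmented:
    def test_noiseless_exact(self):
        x = np.array([1.0, 1.5, 2.0, 2.5, 3.0, 3.5])
        y = np.array([3.0, 4.0, 5.0, 5.25, 5.5, 5.75])
        fit = fit_segmented(x, y)
        assert fit.psi == pytest.approx(2.0, abs=1e-8)
        assert fit.slope_before == pytest.approx(2.0, abs=1e-8)
        assert fit.slope_after == pytest.approx(0.5, abs=1e-8)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert fit.converged

    def test_translation_invariance(self):
        x = np.array([1.0, 1.5, 2.0, 2.5, 3.0, 3.5])
        y = np.array([3.0, 4.0, 5.0, 5.25, 5.5, 5.75])
        a = fit_segmented(x, y)
        b = fit_segmented(x, y + 7.0)
        assert b.psi == pytest.approx(a.psi, abs=1e-8)
        assert b.slope_before == pytest.approx(a.slope_before, abs=1e-8)
        assert list(b.intercepts.values())[0] == pytest.approx(
            list(a.intercepts.values())[0] + 7.0, abs=1e-8)

    def test_matches_grid_oracle_on_noisy_instance(self):
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0.5, 4.0, 30))
        y = 1.0 + 2.0 * x - 1.5 * np.clip(x - 2.2, 0.0, None) \
            + rng.normal(0.0, 0.1, 30)
        fit = fit_segmented(x, y)
        psi_g, rss_g, res = grid_oracle(x, y)
        assert abs(fit.psi - psi_g) <= res
        assert fit.rss <= rss_g + 1e-8

    def test_per_plant_intercepts_recovered(self):
        x = np.tile([1.0, 1.5, 2.0, 2.5, 3.0, 3.5], 3)
        pid = np.repeat(["a", "b", "c"], 6)
        offsets = {"a": 0.0, "b": 1.0, "c": -0.5}
        y = np.array([offsets[p] for p in pid]) + 2.0 * x \
            - 1.5 * np.clip(x - 2.0, 0.0, None) + 1.0
        fit = fit_segmented(x, y, pid)
        assert fit.psi == pytest.approx(2.0, abs=1e-8)
        for p, off in offsets.items():
            assert fit.intercepts[p] == pytest.approx(1.0 + off, abs=1e-8)

    def test_continuity_at_breakpoint(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0.5, 4.0, 40))
        y = 0.5 + 1.5 * x - 1.0 * np.clip(x - 2.0, 0.0, None) \
            + rng.normal(0.0, 0.15, 40)
        fit = fit_segmented(x, y)
        eps = 1e-10
        below = fit.predict(fit.psi - eps)
        above = fit.predict(fit.psi + eps)
        assert abs(above - below) < 1e-8

    def test_too_few_distinct_x_raises(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_segmented([1.0, 1.0, 2.0, 3.0], [1.0, 1.1, 2.0, 3.0])

    def test_no_slope_change_flagged(self):
        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(0.5, 4.0, 30))
        y = 1.0 + 2.0 * x  # exactly linear
        fit = fit_segmented(x, y)
        assert "no-slope-change" in fit.flags or abs(fit.slope_change) < 1e-8

    def test_psi_se_positive_on_noisy_data(self):
        rng = np.random.default_rng(3)
        x = np.tile([0.9, 1.5, 2.1, 2.7, 3.3, 3.9], 5)
        pid = np.repeat(np.arange(5), 6)
        y = 1.0 + 2.5 * x - 2.0 * np.clip(x - 2.0, 0.0, None) \
            + rng.normal(0.0, 0.2, 30)
        fit = fit_segmented(x, y, pid)
        assert fit.psi_se > 0.0
        assert fit.slope_before_se > 0.0


class TestProfileRss:
    def test_minimum_at_true_breakpoint_noiseless(self):
        x = np.tile([1.0, 1.5, 2.0, 2.5, 3.0, 3.5], 2)
        y = 1.0 + 2.0 * x - 1.5 * np.clip(x - 2.0, 0.0, None)
        grid = np.linspace(1.2, 3.2, 41)
        rss = profile_rss(x, y, None, grid)
        assert grid[int(np.argmin(rss))] == pytest.approx(2.0, abs=0.05)
        assert profile_rss(x, y, None, 2.0) == pytest.approx(0.0, abs=1e-20)


class TestDaviesTest:
    def test_strong_breakpoint_significant(self):
        rng = np.random.default_rng(4)
        x = np.tile([0.91, 1.50, 2.09, 2.69, 3.28, 3.87], 5)
        pid = np.repeat(np.arange(5), 6)
        y = rng.normal(0.0, 0.3, 5)[pid] + 1.0 + 2.5 * x \
            - 2.0 * np.clip(x - 2.0, 0.0, None) + rng.normal(0.0, 0.15, 30)
        with pytest.warns(RuntimeWarning):  # 6 distinct levels shrink the grid
            res = davies_test(x, y, pid)
        assert res.p_value < 0.05

    def test_exact_linear_noiseless_p_one(self):
        x = np.linspace(0.5, 4.0, 20)
        y = 1.0 + 2.0 * x
        res = davies_test(x, y)
        assert res.p_value == 1.0
        assert np.allclose(res.statistics, 0.0)

    def test_grid_reduction_warns(self):
        x = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 3)
        rng = np.random.default_rng(5)
        y = x + rng.normal(0.0, 0.1, 15)
        with pytest.warns(RuntimeWarning, match="K="):
            res = davies_test(x, y, grid_size=10)
        assert len(res.grid) == 3

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            x = np.sort(rng.uniform(0.5, 4.0, 25))
            y = x + rng.normal(0.0, 0.3, 25)
            assert 0.0 <= davies_test(x, y).p_value <= 1.0

    def test_monotone_power_in_slope_change(self):
        """Empirical rejection rate should not decrease as the planted
        slope change grows (one adjacent inversion tolerated)."""
        rng = np.random.default_rng(8)
        rates = []
        for beta2 in (0.0, 0.5, 1.0, 2.0):
            rej = 0
            for _ in range(120):
                x = np.sort(rng.uniform(0.5, 4.0, 30))
                y = 1.0 + 2.0 * x - beta2 * np.clip(x - 2.0, 0.0, None) \
                    + rng.normal(0.0, 0.2, 30)
                if davies_test(x, y).p_value < 0.05:
                    rej += 1
            rates.append(rej / 120)
        inversions = sum(1 for a, b in zip(rates, rates[1:]) if b < a)
        assert inversions <= 1
        assert rates[-1] > rates[0]
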