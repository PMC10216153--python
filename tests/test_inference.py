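import numpy as np
import pytest

from cansurv.inference import (classify_plausible_trend, conditional_draws,
                               derivative_draws, detect_breakpoints,
                               repaired_conditional_draws)
from cansurv.trend import PosteriorCurves


def curves(draws, start=1990.0, measure="5-year"):
    draws = np.asarray(draws, dtype=float)
    grid = start + np.arange(draws.shape[1])
    return PosteriorCurves(grid=grid, draws=draws, measure=measure)


def poly_curves(n_draws, grid, coef_sampler, rng):
    """Draws from a random polynomial family y = sum c_k x^k (x centred)."""
    x = grid - grid.mean()
    out = np.empty((n_draws, grid.size))
    coefs = []
    for i in range(n_draws):
        c = coef_sampler(rng)
        coefs.append(c)
        out[i] = np.polyval(c[::-1], x)
    return out, coefs, x


class TestConditionalDraws:
    def test_identical_models_give_100(self):
        pc = curves(np.random.default_rng(0).uniform(40, 80, (50, 6)))
        ratio = conditional_draws(pc, pc)
        np.testing.assert_allclose(ratio.draws, 100.0)

    def test_degenerate_arithmetic(self):
        r = conditional_draws(curves(np.full((10, 4), 60.0)),
                              curves(np.full((10, 4), 80.0)))
        np.testing.assert_allclose(r.draws, 75.0)

    def test_product_identity_per_draw(self):
        rng = np.random.default_rng(1)
        pc5 = curves(rng.uniform(30, 70, (200, 8)))
        pc1 = curves(rng.uniform(60, 95, (200, 8)))
        ratio = conditional_draws(pc5, pc1)
        np.testing.assert_allclose(pc1.draws * ratio.draws / 100.0,
                                   pc5.draws, rtol=1e-13)

    def test_interval_matches_order_statistics_oracle(self):
        rng = np.random.default_rng(2)
        pc5 = curves(rng.uniform(30, 70, (4000, 5)))
        pc1 = curves(rng.uniform(60, 95, (4000, 5)))
        ratio = conditional_draws(pc5, pc1)
        lo, hi = np.percentile(ratio.draws, [2.5, 97.5], axis=0)
        direct = 100.0 * pc5.draws / pc1.draws
        for j in range(5):
            col = np.sort(direct[:, j])
            assert lo[j] == pytest.approx(np.percentile(col, 2.5), rel=1e-12)
            assert hi[j] == pytest.approx(np.percentile(col, 97.5), rel=1e-12)

    def test_grid_mismatch_rejected(self):
        a = curves(np.full((10, 4), 50.0), start=1990.0)
        b = curves(np.full((10, 4), 50.0), start=1991.0)
        with pytest.raises(ValueError, match="grids"):
            conditional_draws(a, b)

    def test_nonpositive_denominator_flagged(self):
        a = curves(np.full((10, 4), 50.0))
        bad = np.full((10, 4), 80.0)
        bad[3, 2] = -0.5
        with pytest.raises(ValueError, match="positive"):
            conditional_draws(a, curves(bad))

    def test_random_repairing_insensitive_in_distribution(self):
        rng = np.random.default_rng(3)
        pc5 = curves(rng.normal(50, 2, (8000, 4)))
        pc1 = curves(rng.normal(80, 2, (8000, 4)))
        a = conditional_draws(pc5, pc1)
        b = repaired_conditional_draws(pc5, pc1, seed=0)
        np.testing.assert_allclose(np.median(a.draws, axis=0),
                                   np.median(b.draws, axis=0), atol=0.15)


class TestDerivativeDraws:
    def test_linear_family_first_derivative_exact(self):
        grid = 1990.0 + np.arange(12)
        rng = np.random.default_rng(4)
        draws, coefs, _ = poly_curves(
            60, grid, lambda r: np.array([r.normal(50, 5), r.normal(0, 1)]),
            rng)
        d1 = derivative_draws(curves(draws), 1)
        slopes = np.broadcast_to(np.array([c[1] for c in coefs])[:, None],
                                 d1.draws.shape)
        np.testing.assert_allclose(d1.draws, slopes, atol=1e-9)
        d2 = derivative_draws(curves(draws), 2)
        np.testing.assert_allclose(d2.draws, 0.0, atol=1e-9)

    def test_quadratic_family_second_derivative_exact(self):
        grid = 1990.0 + np.arange(12)
        rng = np.random.default_rng(5)
        draws, coefs, _ = poly_curves(
            60, grid,
            lambda r: np.array([r.normal(50, 5), r.normal(0, 1),
                                r.normal(0, 0.2)]), rng)
        d2 = derivative_draws(curves(draws), 2)
        want = np.broadcast_to(
            2.0 * np.array([c[2] for c in coefs])[:, None], d2.draws.shape)
        np.testing.assert_allclose(d2.draws, want, atol=1e-9)

    def test_cubic_family_matches_analytic_derivative_oracle(self):
        grid = 1980.0 + np.arange(15)
        rng = np.random.default_rng(6)
        draws, coefs, x = poly_curves(
            40, grid,
            lambda r: r.normal(0, 1, 4) * np.array([50, 1, 0.1, 0.01]), rng)
        d1 = derivative_draws(curves(draws), 1)
        # central differences of a cubic: f'(x) + h^2/6 f''' with h = 1
        for i, c in enumerate(coefs):
            analytic = c[1] + 2 * c[2] * x[1:-1] + 3 * c[3] * x[1:-1] ** 2
            np.testing.assert_allclose(d1.draws[i], analytic + c[3],
                                       atol=1e-9)

    def test_boundary_years_dropped(self):
        pc = curves(np.zeros((5, 10)))
        d = derivative_draws(pc, 1)
        assert d.grid[0] == pc.grid[1] and d.grid[-1] == pc.grid[-2]

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            derivative_draws(curves(np.zeros((5, 10))), 3)


def summary_from_bands(grid_start, lows, highs, order=1, measure="m"):
    """Build a DerivativeSummary-like input from explicit CrI bands."""
    from cansurv.inference import DerivativeSummary

    lows = np.asarray(lows, dtype=float)
    highs = np.asarray(highs, dtype=float)
    grid = grid_start + np.arange(lows.size)
    med = 0.5 * (lows + highs)
    return DerivativeSummary(order=order, grid=grid, median=med,
                             ci_low=lows, ci_high=highs,
                             draws=np.vstack([lows, highs]), measure=measure)


class TestPlausibleTrend:
    def test_flat_noisy_series_no_segments(self):
        lows = np.full(20, -0.5)
        highs = np.full(20, 0.5)
        d1 = summary_from_bands(1975.0, lows, highs)
        assert classify_plausible_trend(d1) == []

    def test_positive_window_one_segment(self):
        lows = np.full(30, -0.2)
        highs = np.full(30, 0.3)
        lows[5:26] = 0.1   # 1995..2015 inclusive
        d1 = summary_from_bands(1990.0, lows, highs)
        segs = classify_plausible_trend(d1)
        assert len(segs) == 1
        assert (segs[0].start_year, segs[0].end_year) == (1995.0, 2015.0)
        assert segs[0].sign == "increasing"

    def test_four_point_excursion_rejected_five_retained(self):
        lows = np.full(20, -0.2)
        highs = np.full(20, 0.3)
        lows[2:6] = 0.05    # 4 consecutive grid points
        lows[10:15] = 0.05  # 5 consecutive grid points
        d1 = summary_from_bands(2000.0, lows, highs)
        segs = classify_plausible_trend(d1, min_years=5, run_units="points")
        assert len(segs) == 1
        assert segs[0].start_year == 2010.0

    def test_span_units_reading(self):
        lows = np.full(20, -0.2)
        highs = np.full(20, 0.3)
        lows[2:7] = 0.05    # 5 points = 4-year span
        d1 = summary_from_bands(2000.0, lows, highs)
        assert classify_plausible_trend(d1, 5, "points") != []
        assert classify_plausible_trend(d1, 5, "span") == []

    def test_decreasing_segment_sign(self):
        lows = np.full(10, -0.4)
        highs = np.full(10, -0.1)
        d1 = summary_from_bands(2000.0, lows, highs)
        assert classify_plausible_trend(d1)[0].sign == "decreasing"


class TestBreakpoints:
    def test_linear_truth_no_breakpoints(self):
        grid = 1990.0 + np.arange(12)
        rng = np.random.default_rng(7)
        draws = rng.normal(50, 5, 300)[:, None] + \
            rng.normal(1, 0.1, 300)[:, None] * (grid - 2000.0)[None, :]
        d2 = derivative_draws(curves(draws), 2)
        assert detect_breakpoints(d2) == []

    def test_peak_year_and_tie_break(self):
        lows = np.full(15, -0.05)
        highs = np.full(15, 0.02)
        lows[4:9] = 0.01
        highs[4:9] = np.array([0.2, 0.4, 0.4, 0.3, 0.1])  # tie at years 5, 6
        d2 = summary_from_bands(2000.0, lows, highs, order=2)
        bps = detect_breakpoints(d2)
        assert len(bps) == 1
        assert bps[0].year == 2005.0            # earliest of the tied peak
        assert bps[0].direction == "acceleration"
        assert bps[0].interval == (2004.0, 2008.0)

    def test_two_separated_episodes_chronological(self):
        lows = np.full(30, -0.05)
        highs = np.full(30, 0.05)
        lows[3:8] = 0.1
        highs[3:8] = 0.3
        highs[20:25] = -0.1
        lows[20:25] = -0.3
        d2 = summary_from_bands(1980.0, lows, highs, order=2)
        bps = detect_breakpoints(d2)
        assert [b.direction for b in bps] == ["acceleration", "deceleration"]
        assert bps[0].year < bps[1].year

    def test_short_run_rejected(self):
        lows = np.full(10, -0.05)
        highs = np.full(10, 0.05)
        lows[4:6] = 0.1   # only 2 grid points
        d2 = summary_from_bands(2000.0, lows, highs, order=2)
        assert detect_breakpoints(d2, min_years=3) == []


class TestEquivariance:
    def make_draws(self, rng):
        grid = np.arange(20, dtype=float)
        base = 40 + 15 / (1 + np.exp(-(grid - 10) / 1.5))
        return base[None, :] + rng.normal(0, 0.02, (800, 20))

    def test_translation_equivariance(self):
        rng = np.random.default_rng(8)
        draws = self.make_draws(rng)
        a5 = curves(draws, start=1990.0)
        b5 = curves(draws, start=1997.0)   # shift +7 years
        for fn, order in ((classify_plausible_trend, 1),
                          (detect_breakpoints, 2)):
            ra = fn(derivative_draws(a5, order))
            rb = fn(derivative_draws(b5, order))
            assert len(ra) == len(rb) > 0
            for x, y in zip(ra, rb):
                if order == 1:
                    assert y.start_year - x.start_year == 7.0
                else:
                    assert y.year - x.year == 7.0

    def test_scale_behavior(self):
        rng = np.random.default_rng(9)
        draws = self.make_draws(rng)
        c = 3.0
        d2a = derivative_draws(curves(draws), 2)
        d2b = derivative_draws(curves(c * draws), 2)
        np.testing.assert_allclose(d2b.median, c * d2a.median, rtol=1e-9)
        ba = detect_breakpoints(d2a)
        bb = detect_breakpoints(d2b)
        assert [b.year for b in ba] == [b.year for b in bb]
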