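import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from centipet import calibrate as cal
from centipet import synthetic as syn
from centipet import thresholds as thr
from centipet.errors import InsufficientDataError, ParameterError
from conftest import make_longitudinal_pairs

ANCHORS = cal.AnchorSet(1.1, 2.1)
IDENTITY_EQ = cal.ConversionEquation("id", 1.0, 0.0, 1.0, 4, ANCHORS)


def make_curve(grid, fitted):
    grid = np.asarray(grid)
    fitted = np.asarray(fitted, float)
    return thr.LoessRateCurve(
        grid=grid, fitted_rate=fitted, lower_band=fitted - 1.0,
        upper_band=fitted + 1.0, span=0.75, n_boot=0, ci_level=0.95,
    )


class TestConvertNativeThreshold:
    def test_identity(self):
        assert thr.convert_native_threshold(IDENTITY_EQ, 0.18) == pytest.approx(0.18)

    def test_forced_arithmetic(self):
        eq = cal.ConversionEquation("m", 100.0, 0.0, 1.0, 4, ANCHORS)
        assert thr.convert_native_threshold(eq, 0.18) == pytest.approx(18.0)


class TestSpecificityThreshold:
    def test_constant_values(self):
        assert thr.specificity_threshold([4.2] * 8) == pytest.approx(4.2)

    def test_order_statistics_interpolation(self):
        # rank 1 + 0.95*19 = 19.05 -> between the 19th and 20th order stats
        assert thr.specificity_threshold(np.arange(1, 21)) == pytest.approx(19.05)

    def test_minimum_n(self):
        with pytest.raises(InsufficientDataError):
            thr.specificity_threshold([1, 2, 3, 4])

    @given(
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=-50, max_value=50),
    )
    @settings(max_examples=30, deadline=None)
    def test_affine_equivariance(self, a, b):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 5, 40)
        lhs = thr.specificity_threshold(a * x + b)
        rhs = a * thr.specificity_threshold(x) + b
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    def test_normal_quantile_convergence(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.0, 5.0, 10_000)
        assert thr.specificity_threshold(x) == pytest.approx(1.6448536 * 5.0, abs=0.2)


class TestAnnualizedRate:
    def test_no_change(self):
        p = thr.LongitudinalPair("s", 10.0, 10.0, 2.0)
        assert thr.annualized_rate(p) == 0.0

    def test_forced_arithmetic(self):
        p = thr.LongitudinalPair("s", 0.0, 6.0, 3.0)
        assert thr.annualized_rate(p) == pytest.approx(2.0)

    def test_antisymmetry(self):
        a = thr.LongitudinalPair("s", 3.0, 11.0, 2.5)
        b = thr.LongitudinalPair("s", 11.0, 3.0, 2.5)
        assert thr.annualized_rate(a) == -thr.annualized_rate(b)

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ParameterError):
            thr.LongitudinalPair("s", 0.0, 1.0, 0.0)


class TestLoessRateCurve:
    def test_constant_rates_reproduced(self):
        rng = np.random.default_rng(0)
        pairs = [
            thr.LongitudinalPair(f"s{i}", b, b + 1.0 * 2.0, 2.0)
            for i, b in enumerate(rng.uniform(-10, 40, 60))
        ]
        c = thr.loess_rate_curve(pairs, n_boot=20, seed=0)
        np.testing.assert_allclose(c.fitted_rate[c.supported], 1.0, atol=1e-9)

    def test_linear_truth_recovered(self):
        rng = np.random.default_rng(3)
        baselines = rng.uniform(-10, 40, 300)
        pairs = [
            thr.LongitudinalPair(f"s{i}", b, b + 0.1 * (b - 10.0) * 2.0, 2.0)
            for i, b in enumerate(baselines)
        ]
        c = thr.loess_rate_curve(pairs, n_boot=0, grid_min=-5, grid_max=35, seed=0)
        truth = 0.1 * (c.grid - 10.0)
        interior = c.supported & (c.grid > -3) & (c.grid < 33)
        assert np.all(np.abs(c.fitted_rate[interior] - truth[interior]) < 0.05)

    def test_bands_bracket_fit(self, dip_rate):
        pairs = make_longitudinal_pairs(dip_rate, seed=5)
        c = thr.loess_rate_curve(pairs, n_boot=200, seed=5)
        s = c.supported & ~np.isnan(c.lower_band) & ~np.isnan(c.upper_band)
        ok = (c.lower_band[s] <= c.fitted_rate[s]) & (c.fitted_rate[s] <= c.upper_band[s])
        assert ok.mean() >= 0.95

    def test_band_coverage_of_truth(self):
        # pointwise 95% bootstrap bands should cover a noiseless linear truth
        # at >= 90% of interior grid points on average.  Noise is placed on
        # the follow-up only: with baseline noise the regression target is
        # shifted (errors-in-x correlated with the rate), which is a property
        # of the estimand, not of the band construction under test here.
        linear_rate = syn.RateFunction(
            "piecewise_linear", {"slope": 0.1, "zero_crossing": 10.0}
        )
        coverage = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            base = np.concatenate(
                [rng.normal(0, 8, 180), rng.normal(60, 30, 63)]
            )
            interval = np.clip(rng.normal(3.2, 1.5, base.size), 0.5, None)
            follow = base + linear_rate(base) * interval + rng.normal(0, 2.5, base.size)
            pairs = [
                thr.LongitudinalPair(f"s{i}", b, f, t)
                for i, (b, f, t) in enumerate(zip(base, follow, interval))
            ]
            x = base
            c = thr.loess_rate_curve(pairs, n_boot=500, seed=seed)
            truth = linear_rate(c.grid.astype(float))
            interior = (
                c.supported
                & (c.grid >= np.quantile(x, 0.10))
                & (c.grid <= np.quantile(x, 0.90))
            )
            inside = (c.lower_band[interior] <= truth[interior]) & (
                truth[interior] <= c.upper_band[interior]
            )
            coverage.append(inside.mean())
        assert np.mean(coverage) >= 0.90

    def test_grid_outside_support_is_absent(self):
        rng = np.random.default_rng(2)
        pairs = [
            thr.LongitudinalPair(f"s{i}", b, b + 1.0, 1.0)
            for i, b in enumerate(rng.uniform(0, 20, 40))
        ]
        c = thr.loess_rate_curve(pairs, grid_min=-10, grid_max=30, n_boot=0, seed=0)
        assert np.all(np.isnan(c.fitted_rate[c.grid < 0]))
        assert np.all(np.isnan(c.fitted_rate[c.grid > 20]))

    def test_too_few_pairs(self):
        pairs = [thr.LongitudinalPair(f"s{i}", float(i), float(i), 1.0) for i in range(10)]
        with pytest.raises(InsufficientDataError):
            thr.loess_rate_curve(pairs)


class TestRwThreshold:
    def test_quadratic_dip_grid_rule(self):
        grid = np.arange(-10, 41)
        c = make_curve(grid, 0.02 * (grid - 5.0) ** 2 - 0.5)
        assert thr.rw_threshold(c) == 11  # upward zero at 10, first strictly > 0

    def test_linear_with_min_at_left_edge(self):
        grid = np.arange(-10, 31)
        c = make_curve(grid, 0.5 * (grid - 5.0))
        assert thr.rw_threshold(c) == 6

    def test_everywhere_positive_returns_leftmost_with_warning(self):
        grid = np.arange(0, 20)
        c = make_curve(grid, 1.0 + 0.1 * grid)
        with pytest.warns(UserWarning, match="positive at its minimum"):
            assert thr.rw_threshold(c) == 0

    def test_exact_zero_does_not_trigger(self):
        c = make_curve(np.array([0, 1, 2]), np.array([-1.0, 0.0, 1.0]))
        assert thr.rw_threshold(c) == 2

    def test_never_positive_returns_absent(self):
        grid = np.arange(0, 10)
        c = make_curve(grid, np.full(grid.size, -1.0))
        with pytest.warns(UserWarning, match="never rises above zero"):
            assert thr.rw_threshold(c) is None

    def test_grid_shift_equivariance(self):
        grid = np.arange(-10, 41)
        fitted = 0.02 * (grid - 5.0) ** 2 - 0.5
        base = thr.rw_threshold(make_curve(grid, fitted))
        shifted = thr.rw_threshold(make_curve(grid + 7, fitted))
        assert shifted == base + 7

    def test_returned_threshold_has_positive_rate(self, dip_rate):
        # the modification: never return a CL with a non-positive fitted rate
        for seed in range(5):
            pairs = make_longitudinal_pairs(dip_rate, seed=seed)
            c = thr.loess_rate_curve(pairs, n_boot=0, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t = thr.rw_threshold(c)
            assert t is not None
            assert c.fitted_rate[np.where(c.grid == t)[0][0]] > 0

    def test_all_absent_curve_rejected(self):
        c = thr.LoessRateCurve(
            grid=np.arange(0, 5), fitted_rate=np.full(5, np.nan),
            lower_band=np.full(5, np.nan), upper_band=np.full(5, np.nan),
            span=0.75, n_boot=0, ci_level=0.95,
        )
        with pytest.raises(InsufficientDataError):
            thr.rw_threshold(c)


class TestBuildThresholdSet:
    def test_identity_equation_empirical(self, dip_rate):
        pairs = make_longitudinal_pairs(dip_rate, seed=1)
        cfg = thr.ThresholdConfig(n_boot=50, native_threshold=10.0, seed=1)
        rng = np.random.default_rng(1)
        tset = thr.build_threshold_set(IDENTITY_EQ, rng.normal(0, 5, 100), pairs, cfg)
        assert tset.empirical_cl == pytest.approx(10.0)
        assert tset.rw_cl is not None
        assert tset.method_label == "id"

    def test_specificity_matches_normal_quantile(self, dip_rate):
        pairs = make_longitudinal_pairs(dip_rate, seed=2)
        rng = np.random.default_rng(3)
        yc = rng.normal(0.0, 5.0, 10_000)
        cfg = thr.ThresholdConfig(n_boot=50, seed=2)
        tset = thr.build_threshold_set(IDENTITY_EQ, yc, pairs, cfg)
        assert tset.specificity_cl == pytest.approx(8.224268, abs=0.2)

    def test_rw_recovery_quick(self, dip_rate):
        # median over 5 seeds within 10 +/- 3 CL (full 20-seed sweep lives in
        # the acceptance suite)
        recovered = []
        for seed in range(5):
            pairs = make_longitudinal_pairs(dip_rate, seed=seed)
            cfg = thr.ThresholdConfig(n_boot=0, seed=seed)
            c = thr.loess_rate_curve(pairs, n_boot=0, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                recovered.append(thr.rw_threshold(c))
        assert abs(np.median(recovered) - 10.0) <= 3.0

    def test_band_brackets_point_estimate(self, dip_rate):
        pairs = make_longitudinal_pairs(dip_rate, seed=4)
        rng = np.random.default_rng(4)
        cfg = thr.ThresholdConfig(n_boot=200, seed=4)
        tset = thr.build_threshold_set(IDENTITY_EQ, rng.normal(0, 5, 100), pairs, cfg)
        assert tset.rw_band is not None
        lo, hi = tset.rw_band
        assert lo <= hi
        assert lo - 5 <= tset.rw_cl <= hi + 5  # point estimate near the band
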