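"""Incidence rates, Wald rate differences, NNT/NNH and Kaplan-Meier."""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

import brmcda as b
from brmcda.rates import (DAYS_PER_YEAR, ArmEndpointSummary, RateDifference,
                          km_curve, km_difference_curve, nnt, rate_difference)


def _summary(events, py, endpoint="e", arm="active"):
    return ArmEndpointSummary(endpoint, arm, events, py)


class TestRatesAndDifferences:
    def test_rate_arithmetic(self):
        assert _summary(2, 4.0).rate == pytest.approx(5000.0)
        assert _summary(0, 12.5).rate == 0.0

    def test_zero_patient_years_rejected(self):
        with pytest.raises(ValueError):
            _summary(1, 0.0)

    def test_published_rate_reconstruction(self):
        """Printed per-arm rates reproduce the printed differences exactly."""
        assert (264.2 - 227.7) == pytest.approx(36.5, abs=1e-9)
        assert (191.0 - 291.3) == pytest.approx(-100.3, abs=1e-9)

    def test_identical_summaries_give_null_symmetric_ci(self):
        rd = rate_difference(_summary(10, 100.0), _summary(10, 100.0, arm="control"))
        assert rd.delta == 0.0
        assert rd.ci_lo == pytest.approx(-rd.ci_hi)

    def test_wald_interval_matches_parametric_bootstrap(self):
        """Poisson-resampling oracle for the Wald CI (10^5 replicates).

        Bounds agree within 2% of the interval width (the bootstrap
        percentile at these counts carries a small skew shift).
        """
        a = _summary(50, 1000.0)
        c = _summary(30, 1000.0, arm="control")
        rd = rate_difference(a, c)
        assert rd.delta == pytest.approx(200.0)
        rng = np.random.default_rng(0)
        boots = 1e4 * (rng.poisson(50, 100_000) / 1000.0
                       - rng.poisson(30, 100_000) / 1000.0)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        width = rd.ci_hi - rd.ci_lo
        assert abs(lo - rd.ci_lo) < 0.02 * width
        assert abs(hi - rd.ci_hi) < 0.02 * width

    def test_ci_width_is_3_92_standard_errors(self):
        rd = rate_difference(_summary(40, 500.0), _summary(25, 480.0, arm="control"))
        assert rd.ci_hi - rd.ci_lo == pytest.approx(2 * 1.959963984540054 * rd.se)
        assert rd.ci_lo <= rd.delta <= rd.ci_hi

    def test_wald_coverage_over_simulated_trials(self):
        """95% Wald CI covers the true difference 93-97% of the time.

        500 simulated trials with Poisson counts at expected 60 vs 40
        events per arm (d >= 20 throughout at these sizes).
        """
        rng = np.random.default_rng(123)
        py = 2000.0
        true = 1e4 * (0.03 - 0.02)
        covered = 0
        for da, dc in zip(rng.poisson(0.03 * py, 500), rng.poisson(0.02 * py, 500)):
            rd = rate_difference(_summary(int(da), py),
                                 _summary(int(dc), py, arm="control"))
            covered += rd.ci_lo <= true <= rd.ci_hi
        assert 0.93 <= covered / 500 <= 0.97

    def test_rates_invariant_to_time_unit_bookkeeping(self):
        """Days-to-years conversion must cancel out of the rate."""
        days = np.array([100.0, 250.0, 365.25, 40.0])
        py = days.sum() / DAYS_PER_YEAR
        assert _summary(3, py).rate == pytest.approx(
            1e4 * 3 / (days / DAYS_PER_YEAR).sum())

    def test_from_point_and_ci_recovers_se(self):
        rd = RateDifference.from_point_and_ci("e", -100.3, -149.6, -51.0)
        assert rd.se == pytest.approx((149.6 - 51.0) / 3.92, rel=1e-4)
        with pytest.raises(ValueError):
            RateDifference.from_point_and_ci("e", 5.0, 10.0, 20.0)


class TestNNT:
    def test_primary_composite_example(self):
        rd = RateDifference("primary", -120.0, 45.0, -208.0, -32.0)
        assert nnt(rd) == pytest.approx(1e4 / 120.0)  # ~83.3 PY per event prevented

    def test_unit_case(self):
        rd = RateDifference("e", -10_000.0, 1.0, -10_002.0, -9998.0)
        assert nnt(rd) == pytest.approx(1.0)

    def test_null_difference_flagged_as_infinite_not_raised(self):
        rd = RateDifference("e", 0.0, 1.0, -1.96, 1.96)
        assert math.isinf(nnt(rd))

    def test_sign_bookkeeping_uses_magnitude_only(self):
        """A benefit endpoint in excess (positive delta) is an NNH-style count."""
        harm = RateDifference("e", 40.0, 16.0, 8.0, 72.0)
        benefit = RateDifference("e", -40.0, 16.0, -72.0, -8.0)
        assert nnt(harm) == nnt(benefit) == pytest.approx(250.0)


class TestKaplanMeier:
    def test_no_censoring_reduces_to_empirical_cdf(self):
        rng = np.random.default_rng(7)
        times = rng.exponential(200, 400).round(1)
        curve = km_curve(times, np.ones(times.size, dtype=bool))
        for t in np.quantile(times, [0.1, 0.5, 0.9]):
            assert curve.cuminc_at(t) == pytest.approx(
                np.mean(times <= t), abs=1e-10)

    def test_all_censored_gives_zero_cumulative_incidence(self):
        curve = km_curve(np.array([10.0, 20.0, 30.0]), np.zeros(3, dtype=bool))
        assert curve.times.size == 0
        assert curve.cuminc_at(25.0) == 0.0

    def test_matches_lifelines_on_censored_fixture(self):
        """Library oracle: product-limit estimate to 1e-10 with ties and censoring."""
        rng = np.random.default_rng(42)
        durations = rng.exponential(300, 100).round(0)  # rounding forces ties
        observed = rng.random(100) < 0.7
        curve = km_curve(durations, observed)
        kmf = KaplanMeierFitter().fit(durations, observed)
        ref = 1.0 - np.asarray(
            kmf.survival_function_at_times(curve.times), dtype=float)
        np.testing.assert_allclose(curve.cuminc, ref, atol=1e-10)

    def test_cuminc_monotone_and_at_risk_nonincreasing(self):
        rng = np.random.default_rng(3)
        curve = km_curve(rng.exponential(100, 200), rng.random(200) < 0.5)
        assert np.all(np.diff(curve.cuminc) >= 0)
        assert np.all((curve.cuminc >= 0) & (curve.cuminc <= 1))
        assert np.all(np.diff(curve.at_risk) <= 0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            km_curve(np.array([]), np.array([], dtype=bool))


class TestKMDifference:
    def _curves(self, seed=0, n=200, scale_a=250.0, scale_c=250.0):
        rng = np.random.default_rng(seed)
        da = np.minimum(rng.exponential(scale_a, n), 400.0)
        dc = np.minimum(rng.exponential(scale_c, n), 400.0)
        return (km_curve(da, da < 400.0), km_curve(dc, dc < 400.0))

    def test_identical_cohorts_give_zero_difference(self):
        rng = np.random.default_rng(1)
        d = rng.exponential(100, 150)
        obs = rng.random(150) < 0.8
        a, c = km_curve(d, obs), km_curve(d, obs)
        diff = km_difference_curve(a, c, at_risk_floor=0.0)
        assert np.allclose(diff["diff"], 0.0)

    def test_zero_floor_disables_truncation(self):
        a, c = self._curves()
        merged = np.union1d(a.times, c.times)
        diff = km_difference_curve(a, c, at_risk_floor=0.0)
        assert diff["time_days"].size == merged.size

    def test_truncation_matches_direct_enumeration(self):
        # heavy event rate so the at-risk fraction actually crosses 10%
        a, c = self._curves(seed=9, scale_a=100.0, scale_c=100.0)
        diff = km_difference_curve(a, c, at_risk_floor=0.10)
        grid = np.union1d(a.times, c.times)
        expected = [t for t in grid if a.at_risk_fraction(t) >= 0.10
                    and c.at_risk_fraction(t) >= 0.10]
        assert diff["time_days"].tolist() == expected
        assert diff["time_days"].size < grid.size  # the floor actually bites

    def test_difference_is_zero_at_time_origin(self):
        a, c = self._curves(seed=5, scale_a=150.0)
        assert a.cuminc_at(0.0) - c.cuminc_at(0.0) == 0.0
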