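"""Monte Carlo propagation: sampling families, ΔS distribution, densities."""

import math

import numpy as np
import pytest
from scipy.stats import norm

import brmcda as b
from brmcda.config import ConfigError, WeightSpec
from brmcda.montecarlo import (MCConfig, density_outputs, ecdf_at,
                               run_monte_carlo, sample_rate_differences,
                               sample_rates, sample_weights)
from brmcda.rates import ArmEndpointSummary, RateDifference


class TestRateSampling:
    def test_gamma_moments_match_poisson_rate_estimator(self):
        summ = ArmEndpointSummary("e", "active", 400, 10_000.0)
        rng = np.random.default_rng(0)
        draws = sample_rates(summ, 200_000, rng)
        se = 1e4 * math.sqrt(400) / 10_000.0  # rate SE per 10 000 PY (= 20)
        assert abs(draws.mean() - 400.0) < 3 * se / math.sqrt(200_000)
        assert abs(draws.var() - se**2) < 0.10 * se**2

    def test_zero_count_arm_uses_positive_fallback(self):
        summ = ArmEndpointSummary("e", "active", 0, 500.0)
        draws = sample_rates(summ, 10_000, np.random.default_rng(1))
        assert (draws > 0).all()  # Jeffreys-style shape 0.5, no point mass at 0

    def test_normal_by_ci_sd_matches_printed_interval(self):
        """SD of draws = CI width / 3.92 (the acute-limb-ischemia row)."""
        rd = RateDifference.from_point_and_ci("ali", -100.3, -149.6, -51.0)
        draws = sample_rate_differences(rd, 1_000_000, np.random.default_rng(2))
        assert abs(draws.std() - (149.6 - 51.0) / 3.92) < 0.02 * draws.std()
        assert abs(draws.mean() - (-100.3)) < 3 * rd.se / 1000

    def test_zero_variance_difference_draws_are_constant(self):
        rd = RateDifference("e", 5.0, 0.0, 5.0, 5.0)
        draws = sample_rate_differences(rd, 100, np.random.default_rng(3))
        assert (draws == 5.0).all()


class TestWeightSampling:
    def test_zero_sd_draws_equal_mean_weight(self):
        spec = WeightSpec("e", 0.64, 0.0)
        draws = sample_weights(spec, 50, np.random.default_rng(0))
        np.testing.assert_allclose(draws, 0.36)

    def test_beta_moment_matching(self):
        spec = WeightSpec("e", 0.64, 0.05, "beta")  # weight mean 0.36, sd 0.05
        draws = sample_weights(spec, 1_000_000, np.random.default_rng(4))
        assert abs(draws.mean() - 0.36) < 0.01 * 0.36
        assert abs(draws.std() - 0.05) < 0.01 * 0.05 + 3 * 0.05 / 1000

    @pytest.mark.parametrize("family", ["beta", "truncated-normal"])
    def test_draws_respect_unit_interval(self, family):
        spec = WeightSpec("e", 0.9, 0.2, family)  # weight mean 0.1, heavy sd
        if family == "beta" and 0.2**2 >= 0.1 * 0.9:
            pytest.skip("infeasible for beta")
        draws = sample_weights(spec, 50_000, np.random.default_rng(5))
        assert draws.min() >= 0.0 and draws.max() <= 1.0

    def test_infeasible_beta_pair_rejected(self):
        spec = WeightSpec("e", 0.5, 0.6, "beta")  # sd^2 > mean(1-mean)
        with pytest.raises(ConfigError, match="infeasible"):
            sample_weights(spec, 10, np.random.default_rng(6))


class TestRunMonteCarlo:
    def _fixed_inputs(self):
        rds = {"a": RateDifference("a", -10.0, 0.0, -10.0, -10.0),
               "b": RateDifference("b", 4.0, 0.0, 4.0, 4.0)}
        ws = {"a": WeightSpec("a", 0.0, 0.0, "fixed"),
              "b": WeightSpec("b", 0.5, 0.0, "fixed")}
        return rds, ws

    def test_degenerate_draws_give_binary_probability_and_zero_width(self):
        rds, ws = self._fixed_inputs()
        out = run_monte_carlo(rds, ws, MCConfig(n_runs=1000, seed=0))
        assert out.mean_delta_s == pytest.approx(-8.0)
        assert out.p_benefit in (0.0, 1.0)
        assert out.ci_hi - out.ci_lo == 0.0

    def test_small_run_count_rejected(self):
        rds, ws = self._fixed_inputs()
        with pytest.raises(ConfigError):
            run_monte_carlo(rds, ws, MCConfig(n_runs=39, seed=0))

    def test_missing_weight_is_configuration_error(self):
        rds, ws = self._fixed_inputs()
        del ws["b"]
        with pytest.raises(ConfigError, match="b"):
            run_monte_carlo(rds, ws, MCConfig(n_runs=1000, seed=0))

    def test_matches_closed_form_normal_oracle(self, published_rds,
                                               published_weights):
        """Fixed weights + Gaussian differences: p = Phi(-mu/sigma)."""
        cfg = MCConfig(n_runs=400_000, seed=7, weight_model="fixed")
        out = run_monte_carlo(published_rds, published_weights, cfg)
        mu = sum((1 - published_weights[k].utility_mean) * published_rds[k].delta
                 for k in published_rds)
        var = sum((1 - published_weights[k].utility_mean) ** 2
                  * published_rds[k].se ** 2 for k in published_rds)
        p = norm.cdf(-mu / math.sqrt(var))
        se = math.sqrt(p * (1 - p) / cfg.n_runs)
        assert abs(out.p_benefit - p) < 3 * se

    def test_mean_converges_to_deterministic_score(self, published_rds,
                                                   published_weights, tree):
        det = b.mcda_score_difference(published_rds, published_weights,
                                      tree, model=1)
        cfg = MCConfig(n_runs=1_000_000, seed=11, weight_model="fixed")
        out = run_monte_carlo(published_rds, published_weights, cfg)
        sigma = math.sqrt(sum((1 - published_weights[k].utility_mean) ** 2
                              * published_rds[k].se ** 2 for k in published_rds))
        assert abs(out.mean_delta_s - det.score_difference) \
            < 3 * sigma / math.sqrt(cfg.n_runs)

    def test_mean_contributions_converge_to_theoretical(self, published_rds,
                                                        published_weights):
        out = run_monte_carlo(published_rds, published_weights,
                              MCConfig(n_runs=500_000, seed=3))
        for k, rd in published_rds.items():
            theo = (1 - published_weights[k].utility_mean) * rd.delta
            assert abs(out.mean_contributions[k] - theo) < 0.2, k

    def test_p_benefit_stable_across_seeds(self, published_rds, published_weights):
        n = 200_000
        p1 = run_monte_carlo(published_rds, published_weights,
                             MCConfig(n_runs=n, seed=1)).p_benefit
        p2 = run_monte_carlo(published_rds, published_weights,
                             MCConfig(n_runs=n, seed=2)).p_benefit
        se = math.sqrt(p1 * (1 - p1) / n)
        assert abs(p1 - p2) < 3 * math.sqrt(2) * se

    def test_widening_weight_sd_does_not_raise_p_benefit(self, published_rds):
        """With a negative mean score, inflating weight variance flattens
        the CDF and cannot push the net-benefit probability up."""
        from brmcda.voyager import itt_weight_specs
        n = 300_000
        narrow = run_monte_carlo(published_rds, itt_weight_specs(0.02),
                                 MCConfig(n_runs=n, seed=9)).p_benefit
        wide = run_monte_carlo(published_rds, itt_weight_specs(0.15),
                               MCConfig(n_runs=n, seed=9)).p_benefit
        assert wide <= narrow + 3 * math.sqrt(narrow * (1 - narrow) / n)

    def test_gamma_by_counts_path_runs_from_summaries(self):
        summaries = {
            "e": (ArmEndpointSummary("e", "active", 50, 1000.0),
                  ArmEndpointSummary("e", "control", 30, 1000.0)),
        }
        ws = {"e": WeightSpec("e", 0.5, 0.0, "fixed")}
        out = run_monte_carlo(summaries, ws,
                              MCConfig(n_runs=100_000, seed=0,
                                       rate_model="gamma-by-counts"))
        assert out.mean_delta_s == pytest.approx(0.5 * 200.0, rel=0.05)

    def test_input_kind_mismatch_rejected(self, published_rds):
        ws = {k: WeightSpec(k, 0.5, 0.0, "fixed") for k in published_rds}
        with pytest.raises(ConfigError):
            run_monte_carlo(published_rds, ws,
                            MCConfig(n_runs=1000, rate_model="gamma-by-counts"))


class TestDensityOutputs:
    def test_cdf_normalization_and_monotonicity(self):
        draws = np.random.default_rng(0).normal(-5, 20, 50_000)
        tab = density_outputs(draws)
        assert tab["cdf"].iloc[0] <= 1e-4
        # left-continuous ECDF: P(X < max) = (n-1)/n, so 1 up to 1/n
        assert tab["cdf"].iloc[-1] >= 1.0 - 1e-3
        assert (np.diff(tab["cdf"]) >= 0).all()

    def test_cdf_at_zero_equals_p_benefit_exactly(self):
        draws = np.random.default_rng(1).normal(-2, 10, 20_000)
        p = float(np.mean(draws < 0))
        assert ecdf_at(draws, 0.0) == p
        tab = density_outputs(draws)
        assert float(tab.loc[tab["x"] == 0.0, "cdf"].iloc[0]) == p

    def test_requires_minimum_sample(self):
        with pytest.raises(ValueError):
            density_outputs(np.zeros(10))
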