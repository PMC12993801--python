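"""Calibration: cost, least squares, DRAM sampler, posterior summaries,
collinearity diagnostics.

The ensemble sampler from emcee serves as the independent oracle for the
posterior that the hand-rolled delayed-rejection sampler targets.
"""

import math

import numpy as np
import pytest
from scipy import stats

from soilc14 import (
    ObservationRecord,
    TwoPoolSeriesParams,
    cost,
    default_init,
    fit_least_squares,
    forward_delta14c,
    run_mcmc,
    summarize_posterior_ages,
    system_age_distribution,
    transit_time_distribution,
)
from soilc14.calibration import (
    PosteriorChain,
    collinearity_from_sensitivity,
    collinearity_index,
)

TRUE = TwoPoolSeriesParams(0.1, 0.005, 0.1)


def make_obs(record, params=TRUE, sd_co2=2.0, sd_soc=8.0, shift=(0.0, 0.0)):
    bulk, resp = forward_delta14c(params, record, 2023)
    return ObservationRecord(
        site="synthetic",
        land_use="forest",
        depth_top_cm=0.0,
        depth_bottom_cm=5.0,
        obs_year=2023,
        d14c_co2=resp + shift[0],
        d14c_soc=bulk + shift[1],
        sd_co2=sd_co2,
        sd_soc=sd_soc,
    )


class TestCost:
    def test_zero_at_generating_parameters(self, bomb_record):
        assert cost(TRUE, make_obs(bomb_record), bomb_record) == pytest.approx(
            0.0, abs=1e-20
        )

    def test_one_sigma_offset_costs_one(self, bomb_record):
        obs = make_obs(bomb_record, shift=(2.0, 0.0))  # 1 sigma on CO2
        assert cost(TRUE, obs, bomb_record) == pytest.approx(1.0, abs=1e-10)

    def test_weighted_sum_of_squares(self, bomb_record):
        # 1 sigma on CO2 (2 permil) plus 2 sigma on SOC (16 permil) -> 1+4
        obs = make_obs(bomb_record, shift=(2.0, -16.0))
        assert cost(TRUE, obs, bomb_record) == pytest.approx(5.0, abs=1e-10)

    def test_excluded_observation_rejected(self, bomb_record):
        obs = make_obs(bomb_record)
        obs.excluded = True
        with pytest.raises(ValueError):
            cost(TRUE, obs, bomb_record)


class TestLeastSquares:
    def test_start_at_optimum_stays(self, bomb_record):
        obs = make_obs(bomb_record)
        res = fit_least_squares(obs, bomb_record, TRUE)
        assert res.cost <= 1e-8

    def test_recovers_observations_from_perturbed_start(self, bomb_record):
        obs = make_obs(bomb_record)
        init = TwoPoolSeriesParams(TRUE.k_fast * 2, TRUE.k_slow * 2, TRUE.alpha)
        res = fit_least_squares(obs, bomb_record, init)
        bulk, resp = forward_delta14c(res.params, bomb_record, 2023)
        # equifinality: parameters need not return to truth, but the fitted
        # Delta14C pair must reproduce the noiseless observations
        assert bulk == pytest.approx(obs.d14c_soc, abs=0.01)
        assert resp == pytest.approx(obs.d14c_co2, abs=0.01)

    def test_never_worse_than_init(self, bomb_record):
        obs = make_obs(bomb_record, shift=(5.0, -11.0))
        init = default_init(obs, bomb_record)
        res = fit_least_squares(obs, bomb_record, init)
        assert res.cost <= cost(init, obs, bomb_record) + 1e-12


class TestMcmc:
    def test_chain_deterministic_under_seed(self, bomb_record):
        obs = make_obs(bomb_record)
        c1 = run_mcmc(obs, bomb_record, TRUE, n_iter=800, seed=42)
        c2 = run_mcmc(obs, bomb_record, TRUE, n_iter=800, seed=42)
        assert np.array_equal(c1.samples, c2.samples)
        assert np.array_equal(c1.costs, c2.costs)
        assert c1.acceptance_rate == c2.acceptance_rate

    def test_different_seeds_differ(self, bomb_record):
        obs = make_obs(bomb_record)
        c1 = run_mcmc(obs, bomb_record, TRUE, n_iter=500, seed=1)
        c2 = run_mcmc(obs, bomb_record, TRUE, n_iter=500, seed=2)
        assert not np.array_equal(c1.samples, c2.samples)

    def test_samples_respect_prior_support(self, bomb_record):
        obs = make_obs(bomb_record)
        chain = run_mcmc(obs, bomb_record, TRUE, n_iter=2000, seed=3)
        kf, ks, a = chain.samples.T
        assert np.all((kf >= 1e-3) & (kf <= 10))
        assert np.all((ks >= 1e-6) & (ks <= 1))
        assert np.all((a >= 0) & (a <= 1))
        assert np.all(ks <= kf)

    def test_flat_likelihood_recovers_uniform_alpha_prior(self, bomb_record):
        # sigma -> infinity: posterior == prior, so alpha ~ U(0,1)
        obs = make_obs(bomb_record, sd_co2=1e9, sd_soc=1e9)
        chain = run_mcmc(obs, bomb_record, TRUE, n_iter=20_000, seed=4)
        # thin heavily: the KS test assumes independent draws
        alpha = chain.post_burn_in()[0][::50, 2]
        assert stats.kstest(alpha, "uniform").pvalue > 0.01

    def test_posterior_matches_ensemble_sampler_oracle(self, bomb_record):
        import emcee

        obs = make_obs(bomb_record)  # noiseless observation of TRUE

        def log_post(th):
            kf, ks, a = math.exp(th[0]), math.exp(th[1]), th[2]
            if not (1e-3 <= kf <= 10 and 1e-6 <= ks <= 1 and 0 <= a <= 1 and ks <= kf):
                return -np.inf
            return -0.5 * cost(TwoPoolSeriesParams(kf, ks, a), obs, bomb_record)

        rng = np.random.default_rng(0)
        nw = 40
        p0 = np.column_stack(
            [
                rng.uniform(math.log(1e-3), math.log(10), nw),
                rng.uniform(math.log(1e-6), math.log(0.05), nw),
                rng.uniform(0.01, 0.99, nw),
            ]
        )
        p0[:, 1] = np.minimum(p0[:, 1], p0[:, 0])
        np.random.seed(12345)  # emcee draws from the global numpy RNG
        sampler = emcee.EnsembleSampler(nw, 3, log_post)
        sampler.run_mcmc(p0, 3000, progress=False)
        flat = sampler.get_chain(discard=1000, thin=10, flat=True)
        sa_oracle = np.array(
            [
                system_age_distribution(
                    TwoPoolSeriesParams(math.exp(t[0]), math.exp(t[1]), t[2])
                ).median
                for t in flat
            ]
        )

        chain = run_mcmc(obs, bomb_record, TRUE, n_iter=30_000, seed=5)
        post, _ = chain.post_burn_in()
        sa_dram = np.array(
            [
                system_age_distribution(TwoPoolSeriesParams(*p)).median
                for p in post[::30]
            ]
        )
        # two samplers of the same posterior: central quantiles agree
        q_o = np.quantile(sa_oracle, [0.25, 0.5, 0.75])
        q_d = np.quantile(sa_dram, [0.25, 0.5, 0.75])
        assert np.all(np.abs(q_d - q_o) / q_o < 0.25)

    def test_start_outside_prior_rejected(self, bomb_record):
        obs = make_obs(bomb_record)
        bad = TwoPoolSeriesParams(0.001, 0.5, 0.2)  # k_slow > k_fast
        with pytest.raises(ValueError):
            run_mcmc(obs, bomb_record, bad, n_iter=100, seed=0)


class TestPosteriorAges:
    def _degenerate_chain(self, params, n=1000):
        samples = np.tile(params.as_tuple(), (n, 1))
        return PosteriorChain(
            samples=samples, costs=np.zeros(n), acceptance_rate=1.0, seed=0
        )

    def test_degenerate_chain_gives_analytic_ages(self):
        chain = self._degenerate_chain(TRUE)
        out = summarize_posterior_ages(chain, n_sub=200, seed=1)
        assert out.tt_sd == pytest.approx(0.0, abs=1e-9)
        assert out.sa_sd == pytest.approx(0.0, abs=1e-9)
        assert out.tt_median == pytest.approx(
            transit_time_distribution(TRUE).median, rel=1e-9
        )
        assert out.sa_median == pytest.approx(
            system_age_distribution(TRUE).median, rel=1e-9
        )

    def test_point_values_within_one_percent_of_analytic(self):
        out = summarize_posterior_ages(self._degenerate_chain(TRUE), seed=2)
        assert abs(out.sa_median / system_age_distribution(TRUE).median - 1) < 0.01

    def test_per_sample_median_below_mean_across_posterior(self, bomb_record):
        obs = make_obs(bomb_record)
        chain = run_mcmc(obs, bomb_record, TRUE, n_iter=3000, seed=6)
        out = summarize_posterior_ages(chain, n_sub=200, seed=7)
        assert out.tt_median < out.tt_mean
        assert out.sa_median < out.sa_mean

    def test_subsample_stability_across_seeds(self, bomb_record):
        obs = make_obs(bomb_record)
        chain = run_mcmc(obs, bomb_record, TRUE, n_iter=10_000, seed=8)
        a = summarize_posterior_ages(chain, n_sub=200, seed=100)
        b = summarize_posterior_ages(chain, n_sub=200, seed=200)
        assert abs(a.sa_median - b.sa_median) / a.sa_median < 0.05
        assert abs(a.tt_median - b.tt_median) / a.tt_median < 0.05

    def test_chain_shorter_than_subsample_rejected(self):
        chain = self._degenerate_chain(TRUE, n=100)
        with pytest.raises(ValueError):
            summarize_posterior_ages(chain, n_sub=200)


class TestCollinearity:
    def test_orthonormal_columns_give_one(self):
        S = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert collinearity_from_sensitivity(S) == pytest.approx(1.0, abs=1e-12)

    def test_identical_columns_give_infinity(self):
        S = np.array([[1.0, 1.0], [2.0, 2.0]])
        assert collinearity_from_sensitivity(S) == math.inf

    def test_zero_sensitivity_column_reported_infinite(self):
        S = np.array([[1.0, 0.0], [0.5, 0.0]])
        assert collinearity_from_sensitivity(S) == math.inf

    def test_full_parameter_set_rank_deficient(self, bomb_record):
        # 2 observations vs 3 parameters: index always > 1
        obs = make_obs(bomb_record)
        rng = np.random.default_rng(9)
        for _ in range(5):
            p = TwoPoolSeriesParams(
                float(np.exp(rng.uniform(np.log(0.05), np.log(1)))),
                float(np.exp(rng.uniform(np.log(1e-3), np.log(0.02)))),
                float(rng.uniform(0.1, 0.5)),
            )
            assert collinearity_index(obs, bomb_record, p) > 1.0

    def test_pairwise_subsets_finite(self, bomb_record):
        obs = make_obs(bomb_record)
        idx = collinearity_index(obs, bomb_record, TRUE, subset=(0, 1))
        assert 1.0 <= idx < math.inf
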