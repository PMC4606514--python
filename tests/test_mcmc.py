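import math

import numpy as np
import pytest

import bayesbpi as b
from bayesbpi.mcmc import (
    ChainConfig,
    PriorSpec,
    SamplerState,
    mh_update_locus,
    predict_gebv,
    run_mcmc,
    sample_marker_effect,
    sample_marker_variance,
    sample_overall_mean,
    sample_residual_variance,
)


class _MeanRng:
    """Stub rng whose normal() returns the mean: exposes the conditional's
    location parameter for exact closed-form checks."""

    def normal(self, loc, scale=None):
        return loc


class TestVariancePrimitives:
    def test_marker_variance_prior_moment(self):
        """At g=0 the draw is x^-2(v+1, S): mean S/(v+1-2) = 0.0429/3.234."""
        rng = np.random.default_rng(0)
        prior = PriorSpec()
        draws = np.array([sample_marker_variance(0.0, 1, prior, rng) for _ in range(30000)])
        expected = 0.0429 / (5.234 - 2.0)
        assert abs(draws.mean() - expected) / expected < 0.05

    def test_marker_variance_shifts_up_with_large_effect(self):
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(1)
        prior = PriorSpec()
        small = np.array([sample_marker_variance(0.0, 1, prior, rng1) for _ in range(2000)])
        large = np.array([sample_marker_variance(10.0, 1, prior, rng2) for _ in range(2000)])
        # stochastic dominance: empirical CDF of the large-effect draws sits right
        for q in (0.1, 0.5, 0.9):
            assert np.quantile(large, q) > np.quantile(small, q)

    def test_marker_variance_reproducible_under_seed(self):
        prior = PriorSpec()
        d1 = sample_marker_variance(0.5, 1, prior, np.random.default_rng(5))
        d2 = sample_marker_variance(0.5, 1, prior, np.random.default_rng(5))
        assert d1 == d2

    def test_residual_variance_zero_scale(self):
        assert sample_residual_variance(np.zeros(10), np.random.default_rng(0)) == 0.0

    def test_residual_variance_concentrates_at_ete_over_df(self):
        n = 5000
        e = np.ones(n) * math.sqrt((n - 4) / n)  # e'e = n - 4
        rng = np.random.default_rng(2)
        draws = np.array([sample_residual_variance(e, rng) for _ in range(2000)])
        assert abs(draws.mean() - 1.0) < 0.05

    def test_residual_variance_needs_n_above_two(self):
        with pytest.raises(ValueError):
            sample_residual_variance(np.ones(2), np.random.default_rng(0))


class TestMeanAndEffect:
    def test_mean_draw_moments(self):
        rng = np.random.default_rng(3)
        n = 50
        y = rng.standard_normal(n)
        y -= y.mean()
        W = np.zeros((n, 1))
        g = np.zeros(1)
        draws = np.array([sample_overall_mean(y, W, g, 2.0, rng) for _ in range(20000)])
        assert abs(draws.mean()) < 3 * math.sqrt(2.0 / n / 20000) * 10
        assert abs(draws.var() - 2.0 / n) / (2.0 / n) < 0.05

    def test_mean_degenerate_variance_returns_adjusted_mean(self):
        y = np.array([1.0, 2.0, 3.0])
        assert sample_overall_mean(y, np.zeros((3, 1)), np.zeros(1), 0.0, None) == 2.0

    def test_effect_conditional_matches_ridge_posterior(self):
        """Conditional location equals w'y_adj/(w'w + sigma_e^2/sigma_g^2)."""
        rng = np.random.default_rng(4)
        n = 30
        w = rng.standard_normal(n)
        y = rng.standard_normal(n)
        state = SamplerState(
            mu=0.0, g=np.array([0.7]), sigma2_g=np.array([0.5]), sigma2_e=2.0,
            e=y - w * 0.7,
        )
        g_new = sample_marker_effect(0, state, w[:, None], y, _MeanRng())
        lam = 2.0 / 0.5
        expected = (w @ y) / (w @ w + lam)
        assert abs(g_new - expected) < 1e-10
        np.testing.assert_allclose(state.e, y - w * g_new, atol=1e-12)

    def test_effect_flat_prior_limit_is_least_squares(self):
        rng = np.random.default_rng(5)
        n = 30
        w = rng.standard_normal(n)
        y = rng.standard_normal(n)
        state = SamplerState(
            mu=0.0, g=np.array([0.0]), sigma2_g=np.array([1e12]), sigma2_e=1.0, e=y.copy()
        )
        g_new = sample_marker_effect(0, state, w[:, None], y, _MeanRng())
        assert abs(g_new - (w @ y) / (w @ w)) < 1e-8

    def test_effect_requires_positive_variance(self):
        state = SamplerState(
            mu=0.0, g=np.zeros(1), sigma2_g=np.zeros(1), sigma2_e=1.0, e=np.zeros(4)
        )
        with pytest.raises(ValueError):
            sample_marker_effect(0, state, np.ones((4, 1)), np.zeros(4), np.random.default_rng(0))


class TestMHUpdate:
    def _state(self, w, y, g0=0.0, s2g=0.0):
        return SamplerState(
            mu=0.0,
            g=np.array([g0]),
            sigma2_g=np.array([s2g]),
            sigma2_e=1.0,
            e=y - w * g0,
        )

    def test_closed_gate_keeps_marker_out(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal(100)
        y = 2.0 * w + rng.standard_normal(100)
        state = self._state(w, y)
        prior = PriorSpec(pi=1.0)
        for _ in range(50):
            s2, g = mh_update_locus(0, state, w[:, None], prior, 10, rng, pi_j=1.0)
        assert s2 == 0.0 and g == 0.0

    def test_open_gate_includes_strong_marker(self):
        rng = np.random.default_rng(1)
        w = rng.standard_normal(300)
        y = 1.0 * w + rng.standard_normal(300)
        state = self._state(w, y)
        prior = PriorSpec(pi=0.0)
        incl = 0
        for _ in range(200):
            s2, _ = mh_update_locus(0, state, w[:, None], prior, 10, rng, pi_j=0.0)
            incl += s2 > 0
        assert incl / 200 > 0.9

    def test_null_marker_rarely_included_at_default_pi(self):
        freqs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            w = rng.standard_normal(300)
            y = rng.standard_normal(300)
            state = self._state(w, y)
            prior = PriorSpec(pi=0.95)
            incl = 0
            for _ in range(100):
                s2, _ = mh_update_locus(0, state, w[:, None], prior, 10, rng, pi_j=0.95)
                incl += s2 > 0
            freqs.append(incl / 100)
        assert np.mean(freqs) < 0.2

    def test_acceptance_likelihood_matches_dense_gaussian(self):
        """The rank-one log-likelihood used in the MH ratio equals the dense
        multivariate-normal evaluation of y_adj ~ N(0, s2 ww' + s2e I)."""
        from scipy.stats import multivariate_normal

        from bayesbpi.mcmc import _locus_loglik

        rng = np.random.default_rng(2)
        n = 8
        w = rng.standard_normal(n)
        y_adj = rng.standard_normal(n)
        c = float(w @ w)
        r = float(w @ y_adj)
        s2e = 1.3
        base = multivariate_normal.logpdf(y_adj, cov=s2e * np.eye(n))
        for s2 in (0.1, 0.7, 2.5):
            dense = multivariate_normal.logpdf(y_adj, cov=s2 * np.outer(w, w) + s2e * np.eye(n))
            np.testing.assert_allclose(
                _locus_loglik(s2, c, r, s2e), dense - base, atol=1e-10
            )

    def test_skip_mode_never_proposes_zero(self):
        rng = np.random.default_rng(3)
        w = rng.standard_normal(50)
        y = 2.0 * w + rng.standard_normal(50)
        state = self._state(w, y, g0=0.5, s2g=0.3)
        prior = PriorSpec(pi=1.0)
        s2, g = mh_update_locus(0, state, w[:, None], prior, 20, rng, pi_j=1.0,
                                gate_mode="skip")
        assert s2 == 0.3  # gate closed every cycle, variance untouched


class TestRunMCMC:
    def test_bayesB_scalar_equals_constant_pi_vector(self):
        rng = np.random.default_rng(0)
        W = rng.standard_normal((60, 30))
        y = W[:, 3] + rng.standard_normal(60)
        cfg = ChainConfig(n_iterations=120, burn_in=20, mh_cycles=5, seed=11)
        s1 = run_mcmc(y, W, PriorSpec(pi=0.95), cfg, method="bayesB")
        s2 = run_mcmc(y, W, PriorSpec(pi=np.full(30, 0.95)), cfg, method="bayesBpi")
        np.testing.assert_array_equal(s1.effect_means, s2.effect_means)
        np.testing.assert_array_equal(s1.inclusion_freq, s2.inclusion_freq)

    def test_residual_consistency_invariant(self):
        rng = np.random.default_rng(1)
        W = rng.standard_normal((80, 40))
        y = W[:, 0] - W[:, 5] + rng.standard_normal(80)
        for method in ("bayesA", "bayesB"):
            cfg = ChainConfig(n_iterations=60, burn_in=10, mh_cycles=4, seed=2)
            _, state = run_mcmc(y, W, PriorSpec(pi=0.9), cfg, method=method,
                                return_state=True)
            resid = y - state.mu - W @ state.g
            assert np.max(np.abs(resid - state.e)) < 1e-8

    def test_conjugate_posterior_oracle_single_marker(self):
        """With one marker and both variances fixed, the chain's posterior
        for g matches the closed-form normal posterior."""
        rng = np.random.default_rng(3)
        n = 100
        w = rng.standard_normal(n)
        y = 0.6 * w + rng.standard_normal(n)
        s2g, s2e = 0.8, 1.0
        lam = s2e / s2g
        post_mean = (w @ y) / (w @ w + lam)
        post_var = s2e / (w @ w + lam)
        cfg = ChainConfig(n_iterations=6000, burn_in=500, seed=4)
        summ = run_mcmc(y - y.mean(), w[:, None], PriorSpec(), cfg, method="bayesA",
                        fix_sigma2_e=s2e, fix_sigma2_g=s2g)
        mc_se = math.sqrt(post_var / summ.n_samples) * 3  # draws autocorrelated -> pad
        assert abs(summ.effect_means[0] - post_mean) < max(4 * mc_se, 0.02)

    def test_pure_noise_shrinks_effects(self, null_dataset):
        """On a pure-noise trait the posterior-mean effects collapse: the
        bulk shrinks to near zero and even the top spurious marker stays
        below its unshrunk single-marker OLS estimate."""
        X = null_dataset.genotypes.codes
        y = null_dataset.phenotypes.values[:, 0]
        W = X - X.mean(axis=0)
        cfg = ChainConfig(n_iterations=400, burn_in=100, mh_cycles=5, seed=5)
        summ = run_mcmc(y, W, PriorSpec(pi=0.95), cfg, method="bayesB")
        ols = (W.T @ (y - y.mean())) / np.sum(W**2, axis=0)
        assert np.percentile(np.abs(summ.effect_means), 95) < 0.05 * np.std(y)
        assert np.max(np.abs(summ.effect_means)) < np.max(np.abs(ols))

    def test_recovers_major_qtl(self, mfp_dataset):
        X = mfp_dataset.genotypes.codes
        y = mfp_dataset.phenotypes.values[:, 0]
        y = (y - y.mean()) / y.std(ddof=1)
        W = X - X.mean(axis=0)
        pi = b.locus_pi_from_data(mfp_dataset.genotypes, y).pi
        cfg = ChainConfig(n_iterations=800, burn_in=200, mh_cycles=5, seed=6)
        summ = run_mcmc(y, W, PriorSpec(pi=pi), cfg, method="bayesBpi")
        assert np.argmax(np.abs(summ.effect_means)) == np.argmax(
            np.abs(mfp_dataset.true_effects)
        )
        assert np.corrcoef(summ.effect_means, mfp_dataset.true_effects)[0, 1] > 0.3

    def test_marker_permutation_equivariance_with_locus_streams(self):
        rng = np.random.default_rng(7)
        W = rng.standard_normal((50, 12))
        y = W[:, 2] + rng.standard_normal(50)
        keys = np.arange(12)
        pi = np.linspace(0.1, 0.95, 12)
        cfg = ChainConfig(n_iterations=80, burn_in=20, mh_cycles=3, seed=8)
        base = run_mcmc(y, W, PriorSpec(pi=pi), cfg, method="bayesBpi", locus_keys=keys)
        perm = rng.permutation(12)
        permd = run_mcmc(y, W[:, perm], PriorSpec(pi=pi[perm]), cfg, method="bayesBpi",
                         locus_keys=keys[perm])
        np.testing.assert_allclose(permd.effect_means, base.effect_means[perm], atol=1e-12)

    def test_nan_response_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            run_mcmc(np.array([1.0, np.nan, 0.0]), np.zeros((3, 1)))


class TestPredict:
    def test_gebv_linear_in_effects_and_mu_flag(self):
        summ = b.PosteriorSummary(
            effect_means=np.array([0.5, -1.0]),
            inclusion_freq=np.array([1.0, 1.0]),
            mu_mean=2.0,
            sigma2_e_mean=1.0,
            n_samples=10,
        )
        W = np.array([[1.0, 0.0], [0.0, 2.0]])
        np.testing.assert_allclose(predict_gebv(summ, W), [0.5, -2.0])
        np.testing.assert_allclose(predict_gebv(summ, W, mu_included=True), [2.5, 0.0])

    def test_column_mismatch_errors(self):
        summ = b.PosteriorSummary(
            effect_means=np.zeros(3), inclusion_freq=np.zeros(3),
            mu_mean=0.0, sigma2_e_mean=1.0, n_samples=1,
        )
        with pytest.raises(ValueError, match="mismatch"):
            predict_gebv(summ, np.zeros((2, 2)))
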