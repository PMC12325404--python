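"""Hierarchical Bayesian estimation: likelihood, priors, recovery, diagnostics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, truncnorm

from truthfx import (
    DesignSpec,
    McmcSettings,
    PriorSpec,
    diagnostics,
    fit_model,
    posterior_summary,
    simulate_dataset,
)
from truthfx.inference import MATCHED_M_PRIOR_MEANS, PosteriorFit, ProbitTruthModel

from conftest import tiny_settings


def hand_table():
    return pd.DataFrame({
        "participant_id": ["a", "a", "b", "b", "b"],
        "statement_id": ["s1", "s2", "s1", "s2", "s3"],
        "repeated": [0, 1, 1, 0, 0],
        "judgment": [1, 1, 0, 0, 1],
    })


class TestLikelihoodCorrectness:
    @pytest.mark.parametrize("variant", [1, 2, 3, 4])
    def test_pointwise_loglik_matches_closed_form(self, variant):
        """The model's pointwise log likelihood equals the Bernoulli-probit
        expression evaluated by hand on a 5-trial table."""
        trials = hand_table()
        model = ProbitTruthModel(trials, variant, PriorSpec.for_variant(variant))
        # hand-constructed draw: mu_p, log sigmas, log m, p, u, z_v
        p = np.array([0.2, 0.7, -0.3])
        u = np.array([0.1, -0.2])
        sigma_v = 0.2
        z_v = np.array([0.5, -1.0, 0.25])
        m = 0.3
        q = np.concatenate([[0.4], np.log([0.8, 0.3, sigma_v]), [np.log(m)], p, u, z_v])

        from truthfx import fluency_shift

        v = sigma_v * z_v
        # trial order follows the table; statements/participants sorted by id
        i_idx = [0, 1, 0, 1, 2]
        j_idx = [0, 0, 1, 1, 1]
        rep = np.array([0, 1, 1, 0, 0], dtype=float)
        y = np.array([1, 1, 0, 0, 1], dtype=float)
        expected = np.empty(5)
        for t in range(5):
            f = fluency_shift(variant, m, p[i_idx[t]])
            eta = (p[i_idx[t]] + rep[t] * (f + v[i_idx[t]]) + u[j_idx[t]] - 0.5) / 0.5
            theta = norm.cdf(eta)
            expected[t] = np.log(theta if y[t] == 1 else 1 - theta)
        got = model.pointwise_loglik(q[None, :])[0]
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_logp_is_prior_plus_likelihood(self):
        trials = hand_table()
        model = ProbitTruthModel(trials, 1, PriorSpec.for_variant(1))
        rng = np.random.default_rng(5)
        q = 0.2 * rng.standard_normal((3, model.dim))
        prior_model = ProbitTruthModel(None, 1, PriorSpec.for_variant(1))
        # same scalar block; random-effect priors added manually
        lp_full = model.logp(q)
        lp_lik = model.pointwise_loglik(q).sum(axis=-1)
        assert np.all(np.isfinite(lp_full))
        # removing the likelihood leaves a quantity independent of y
        flipped = trials.assign(judgment=1 - trials["judgment"])
        model_f = ProbitTruthModel(flipped, 1, PriorSpec.for_variant(1))
        np.testing.assert_allclose(
            lp_full - lp_lik, model_f.logp(q) - model_f.pointwise_loglik(q).sum(axis=-1), atol=1e-10
        )
        assert prior_model.dim == 5


class TestPriorOnlyFit:
    @pytest.fixture(scope="class")
    def prior_fit(self):
        return fit_model(None, 1, settings=tiny_settings(3, draws=2000))

    def test_m_matches_truncated_normal_prior(self, prior_fit):
        draws = prior_fit.posterior()["m"].ravel()
        a = (0.0 - 0.11) / 0.1
        expected_mean = truncnorm.mean(a, np.inf, loc=0.11, scale=0.1)
        expected_sd = truncnorm.std(a, np.inf, loc=0.11, scale=0.1)
        mc = 4 * expected_sd / np.sqrt(len(draws) / 20)  # generous autocorrelation allowance
        assert abs(draws.mean() - expected_mean) < mc
        assert np.all(draws > 0)

    def test_draw_count_and_positivity(self, prior_fit):
        post = prior_fit.posterior()
        assert post["m"].shape == (2, 2000)
        for name in ("sigma_p", "sigma_u", "sigma_v"):
            assert np.all(post[name] > 0)

    def test_mu_p_matches_prior(self, prior_fit):
        draws = prior_fit.posterior()["mu_p"].ravel()
        assert abs(draws.mean() - 0.5) < 0.15
        assert abs(draws.std() - 1.0) < 0.2


class TestRecovery:
    def test_generating_m_inside_hdi(self, small_m1_fit):
        trials, params, fit = small_m1_fit
        summary = posterior_summary(fit)
        assert summary.loc["m", "hdi_lo"] <= params.m <= summary.loc["m", "hdi_hi"]
        assert fit.max_rhat < 1.05

    def test_posterior_mean_error_shrinks_with_participants(self):
        m_true = 0.3
        errors = []
        for n_parts, seed in [(30, 61), (240, 62)]:
            design = DesignSpec(n_statements=20, n_participants=n_parts,
                                sigma_u=0.2, sigma_v=0.05, seed=seed)
            trials, _ = simulate_dataset(design, 1, m_true)
            fit = fit_model(trials, 1, settings=tiny_settings(seed, warmup=200, draws=500))
            errors.append(abs(posterior_summary(fit).loc["m", "mean"] - m_true))
        assert errors[1] < errors[0]

    @pytest.mark.filterwarnings("ignore:MCMC for M1 did not converge")
    def test_zero_participant_variance_detected(self):
        # the scale posterior piles up at zero; its own R-hat is expected to
        # look poor there (the funnel), but the concentration statement holds
        design = DesignSpec(n_statements=16, n_participants=40, sigma_u=0.0, sigma_v=0.0, seed=77)
        trials, _ = simulate_dataset(design, 1, 0.2)
        fit = fit_model(trials, 1, settings=tiny_settings(8))
        summary = posterior_summary(fit)
        assert summary.loc["sigma_u", "hdi_lo"] < 0.05
        assert summary.loc["sigma_u", "mean"] < 0.15


class TestDiagnostics:
    def test_converged_fit_reports_clean_table(self, small_m1_fit):
        _, _, fit = small_m1_fit
        table = diagnostics(fit)
        assert {"rhat", "ess", "rhat_ok", "ess_ok"} <= set(table.columns)
        assert table.loc["m", "rhat"] < 1.05
        assert table.loc["m", "ess"] > 200

    def test_split_chains_fail_rhat(self, small_m1_fit):
        """Chains stuck at different constants must blow up R-hat."""
        _, _, fit = small_m1_fit
        broken = dataclasses.replace(fit, _diag=None)
        broken.unconstrained = fit.unconstrained.copy()
        broken.unconstrained[0, :, 4] = np.log(0.05)
        broken.unconstrained[1, :, 4] = np.log(0.6)
        assert broken.max_rhat > 1.5
        assert not broken.converged

    def test_nonconvergence_warns(self):
        design = DesignSpec(n_statements=8, n_participants=10, seed=2)
        trials, _ = simulate_dataset(design, 1, 0.1)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fit_model(trials, 1, settings=McmcSettings(chains=2, warmup=10, draws=30, seed=1))


class TestPosteriorSummary:
    def test_symmetric_draws_hdi_close_to_quantiles(self, small_m1_fit):
        _, _, fit = small_m1_fit
        summary = posterior_summary(fit)
        draws = fit.posterior()["m"].ravel()
        q = np.quantile(draws, [0.025, 0.975])
        width = q[1] - q[0]
        assert summary.loc["m", "hdi_lo"] == pytest.approx(q[0], abs=0.3 * width)
        assert summary.loc["m", "hdi_hi"] == pytest.approx(q[1], abs=0.3 * width)

    def test_realized_variance_rows_present(self, small_m1_fit):
        _, _, fit = small_m1_fit
        summary = posterior_summary(fit)
        assert {"var_u", "var_v"} <= set(summary.index)
        assert summary.loc["var_u", "mean"] > 0

    def test_prior_predictive_effect_band(self):
        """Calibrated priors imply average truth effects in the 0-0.15 band."""
        from truthfx import implied_truth_effect

        rng = np.random.default_rng(13)
        a = -0.11 / 0.1
        ms = truncnorm.rvs(a, np.inf, loc=0.11, scale=0.1, size=50, random_state=rng)
        effects = [implied_truth_effect(1, m) for m in ms]
        assert 0.0 < np.mean(effects) < 0.15

    def test_variant_specific_prior_means(self):
        for variant, mean in MATCHED_M_PRIOR_MEANS.items():
            assert PriorSpec.for_variant(variant).m_mean == mean
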