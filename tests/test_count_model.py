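"""Errors-in-variables NB model: sampler, diagnostics, DIC, selection."""

import numpy as np
import pandas as pd
import pytest

import coldstun as cs
from coldstun.count_model import (
    ConvergenceError,
    MeasurementErrorSpec,
    ModelSpec,
    SamplerSettings,
    _acf,
    _pearson_dispersion,
    backward_select,
    derive_homoscedastic_sd,
    dic,
    fit_nb_eiv,
    nb_logpmf,
    overdispersion_stat,
    residual_acf,
    sample_nb,
)
from coldstun.data_io import HatchlingSeries


class TestDeriveHomoscedasticSd:
    def test_hand_arithmetic(self):
        h = HatchlingSeries(np.arange(2000, 2010),
                            [0, 0, 0, 0, 0, 10, 10, 10, 10, 10])
        assert derive_homoscedastic_sd(h) == pytest.approx(np.sqrt(250 / 9))

    def test_constant_tail_gives_zero(self):
        h = HatchlingSeries(np.arange(2000, 2012), [5] * 12)
        assert derive_homoscedastic_sd(h) == 0.0
        with pytest.raises(ValueError):
            MeasurementErrorSpec("homoscedastic", 0.0)  # 0 is unusable downstream

    def test_short_series_errors(self):
        h = HatchlingSeries(np.arange(2000, 2005), [1, 2, 3, 4, 5])
        with pytest.raises(ValueError):
            derive_homoscedastic_sd(h)


class TestNbPrimitives:
    def test_logpmf_normalizes(self):
        ys = np.arange(0, 400)
        total = np.exp(nb_logpmf(ys, 12.0, 2.5)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_sampler_moments(self):
        rng = np.random.default_rng(0)
        mu, k = 20.0, 3.0
        y = sample_nb(rng, np.full(20000, mu), k)
        assert y.mean() == pytest.approx(mu, rel=0.03)
        assert y.var() == pytest.approx(mu + mu**2 / k, rel=0.1)


class TestFitNbEiv:
    def test_posterior_structure_and_determinism(self, quick_fit):
        fit = quick_fit
        s = fit.summary
        assert (s["q025"] <= s["mean"]).all() and (s["mean"] <= s["q975"]).all()
        assert (fit.mu_draws > 0).all()
        assert fit.summary.loc["k", "mean"] > 0
        # original-scale slope is the standardized slope un-scaled
        assert np.allclose(
            fit.draws["beta_sst_min_orig"],
            fit.draws["beta_sst_min"] / fit.x_sd["sst_min"],
        )

    def test_same_seed_identical_draws(self, default_scenario):
        tr = default_scenario.truth
        X = pd.DataFrame({"sst_min": tr.x_obs})
        spec = ModelSpec(covariates=("sst_min",),
                         error={"sst_min": MeasurementErrorSpec("heteroscedastic", tr.err_sd)})
        a = fit_nb_eiv(spec, default_scenario.strandings, X,
                       settings=SamplerSettings.reduced(), seed=21)
        b = fit_nb_eiv(spec, default_scenario.strandings, X,
                       settings=SamplerSettings.reduced(), seed=21)
        assert np.array_equal(a.draws["beta0"], b.draws["beta0"])
        assert np.array_equal(a.mu_draws, b.mu_draws)

    def test_default_settings_converge(self, default_scenario):
        """Full-length chains meet split-R-hat < 1.01 and ESS > 400."""
        tr = default_scenario.truth
        X = pd.DataFrame({"sst_min": tr.x_obs})
        spec = ModelSpec(covariates=("sst_min",),
                         error={"sst_min": MeasurementErrorSpec("heteroscedastic", tr.err_sd)})
        fit = fit_nb_eiv(spec, default_scenario.strandings, X,
                         settings=SamplerSettings(), seed=2)
        assert fit.diagnostics["converged"]
        assert fit.diagnostics["rhat_max"] < 1.01
        assert fit.diagnostics["ess_min"] > 400

    def test_nonconvergence_raises_with_diagnostics(self, default_scenario):
        tr = default_scenario.truth
        X = pd.DataFrame({"sst_min": tr.x_obs})
        spec = ModelSpec(covariates=("sst_min",),
                         error={"sst_min": MeasurementErrorSpec("heteroscedastic", tr.err_sd)})
        harsh = SamplerSettings(n_steps=1200, n_burn=600, ess_min=1e9,
                                on_nonconvergence="raise")
        with pytest.raises(ConvergenceError) as err:
            fit_nb_eiv(spec, default_scenario.strandings, X, settings=harsh, seed=0)
        assert "ess_min" in err.value.diagnostics

    def test_zero_variance_covariate_rejected(self, default_scenario):
        X = pd.DataFrame({"sst_min": np.ones(35)})
        with pytest.raises(ValueError, match="zero variance"):
            fit_nb_eiv(ModelSpec(covariates=("sst_min",)),
                       default_scenario.strandings, X,
                       settings=SamplerSettings.reduced(), seed=0)

    def test_tiny_error_sd_matches_naive_fit(self, default_scenario):
        """EIV collapses to the no-error fit as the measurement SDs vanish."""
        tr = default_scenario.truth
        X = pd.DataFrame({"sst_min": tr.x_obs})
        tiny = ModelSpec(
            covariates=("sst_min",),
            error={"sst_min": MeasurementErrorSpec("heteroscedastic",
                                                   np.full(35, 1e-4))},
        )
        none = ModelSpec(covariates=("sst_min",))
        f1 = fit_nb_eiv(tiny, default_scenario.strandings, X,
                        settings=SamplerSettings.reduced(), seed=5)
        f2 = fit_nb_eiv(none, default_scenario.strandings, X,
                        settings=SamplerSettings.reduced(), seed=5)
        a = f1.summary.loc["beta_sst_min_orig", "mean"]
        b = f2.summary.loc["beta_sst_min_orig", "mean"]
        assert a == pytest.approx(b, abs=0.08)  # within MCMC error


class TestDiagnostics:
    def test_zero_residuals_give_zero_dispersion(self):
        mu = np.array([3.0, 7.0, 1.0, 10.0, 4.0])
        assert _pearson_dispersion(mu, mu, 5.0, 2) == 0.0

    def test_gross_misspecification_inflates_dispersion(self):
        """NB data scored as if near-Poisson: dispersion ≫ 1."""
        rng = np.random.default_rng(0)
        mu = np.full(200, 30.0)
        y = sample_nb(rng, mu, 0.3)  # heavy overdispersion
        assert _pearson_dispersion(y, mu, 1e6, 1) > 3.0

    def test_overdispersion_near_one_for_quick_fit(self, quick_fit):
        assert 0.4 < overdispersion_stat(quick_fit) < 2.0

    def test_acf_lag0_and_alternating(self):
        assert _acf(np.array([1.0, 2.0, 1.5, 3.0]), 2)[0] == 1.0
        alt = np.tile([1.0, -1.0], 30)
        assert _acf(alt, 3)[1] == pytest.approx(-1.0, abs=0.05)

    def test_iid_residual_acf_within_white_noise_bands(self, quick_fit):
        acf = residual_acf(quick_fit, max_lag=8)
        n = quick_fit.n_obs
        assert acf[0] == 1.0
        assert (np.abs(acf[1:]) < 2.5 / np.sqrt(n)).mean() >= 0.75


class TestDic:
    def test_identical_fits_identical_dic(self, quick_fit):
        assert dic(quick_fit) == dic(quick_fit)

    def test_informative_covariate_beats_intercept_only(self, default_scenario):
        tr = default_scenario.truth
        X = pd.DataFrame({"sst_min": tr.x_obs})
        spec = ModelSpec(covariates=("sst_min",),
                         error={"sst_min": MeasurementErrorSpec("heteroscedastic", tr.err_sd)})
        f1 = fit_nb_eiv(spec, default_scenario.strandings, X,
                        settings=SamplerSettings.reduced(), seed=1)
        f0 = fit_nb_eiv(ModelSpec(), default_scenario.strandings, None,
                        settings=SamplerSettings.reduced(), seed=1)
        assert dic(f1) < dic(f0)

    def test_effective_parameters_near_count_in_gaussian_limit(self):
        """Large counts, no latents: pD ≈ number of sampled parameters."""
        rng = np.random.default_rng(4)
        n = 150
        x = rng.standard_normal(n)
        mu = np.exp(5.0 + 0.4 * x)
        y = sample_nb(rng, mu, 50.0)
        X = pd.DataFrame({"x": x})
        fit = fit_nb_eiv(ModelSpec(covariates=("x",)), y, X,
                         settings=SamplerSettings.reduced(), seed=4)
        d_bar = float(np.mean(fit.deviance_draws))
        p_d = dic(fit) - d_bar
        assert 1.0 < p_d < 6.0  # 3 sampled parameters


def test_fitted_band_covers_true_means(eiv_replicates):
    """≈95% of the true μ_t fall inside the 95% credible band for μ."""
    pooled = eiv_replicates["band_coverage"].mean()
    assert 0.85 <= pooled <= 0.999


class TestBackwardSelect:
    def test_null_hatchling_term_dropped_in_most_seeds(self):
        """β2 = 0 in truth: selection discards the hatchling covariate in a
        majority of scenario realizations (its lag trend is collinear with
        warming, so occasional spurious retention is expected)."""
        drops = 0
        for i in range(5):
            sc = cs.make_scenario(cs.ScenarioParams(seed=8000 + i))
            tr = sc.truth
            X = pd.DataFrame({"sst_min": tr.x_obs,
                              "hatchlings_lag_avg": tr.hatch_lag_avg})
            spec = ModelSpec(
                covariates=("sst_min", "hatchlings_lag_avg"),
                error={
                    "sst_min": MeasurementErrorSpec("heteroscedastic", tr.err_sd),
                    "hatchlings_lag_avg": MeasurementErrorSpec(
                        "homoscedastic", derive_homoscedastic_sd(sc.hatchlings)
                    ),
                },
            )
            res = backward_select(spec, sc.strandings, X,
                                  settings=SamplerSettings.reduced(), seed=i)
            assert "sst_min" in res.final_spec.covariates
            assert "(intercept)" in set(res.table["model"])  # baseline tabled
            drops += "hatchlings_lag_avg" not in res.final_spec.covariates
        assert drops >= 3

    def test_single_informative_covariate_kept(self, default_scenario):
        tr = default_scenario.truth
        X = pd.DataFrame({"sst_min": tr.x_obs})
        spec = ModelSpec(covariates=("sst_min",),
                         error={"sst_min": MeasurementErrorSpec("heteroscedastic", tr.err_sd)})
        res = backward_select(spec, default_scenario.strandings, X,
                              settings=SamplerSettings.reduced(), seed=2)
        assert res.final_spec.covariates == ("sst_min",)
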