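"""Random-regression fitting, plasticity extraction and support tests."""

import numpy as np
import pandas as pd
import pytest

from thermoplast.mixed import fit_lmm_gaussian
from thermoplast.reaction_norms import (
    ReactionNormFit,
    compare_random_slope_support,
    extract_population_plasticity,
    fit_random_regression,
    logit_slope_to_percentage_points,
    predict_reaction_norms,
)
from thermoplast.synthetic_data import simulate_random_regression

TEMPS = np.array([-1.5, -0.5, 0.5, 1.5])


def small_table(rng, **kw):
    kw.setdefault("n_populations", 12)
    kw.setdefault("n_individuals", 5)
    table, truth = simulate_random_regression(rng, **kw)
    return table, truth


class TestGaussianFit:
    def test_noiseless_identical_populations(self):
        t = np.tile(TEMPS, 20)
        pop = np.repeat([f"p{i}" for i in range(5)], 16)
        y = 10.0 + 2.0 * t
        X = np.column_stack([np.ones_like(t), t])
        fit = fit_lmm_gaussian(y, X, pop, t)
        np.testing.assert_allclose(fit.beta, [10.0, 2.0], atol=1e-6)
        assert fit.sd_slope == pytest.approx(0.0, abs=1e-6)
        assert fit.boundary  # variance at the zero boundary, not an exception

    def test_single_population_reduces_to_ols(self, rng):
        t = np.tile(TEMPS, 10)
        y = 3.0 + 0.7 * t + rng.normal(0, 1, t.size)
        X = np.column_stack([np.ones_like(t), t])
        fit = fit_lmm_gaussian(y, X, np.repeat("a", t.size), t)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        total = fit.beta + fit.ranef[["intercept_dev", "slope_dev"]].iloc[0].to_numpy()
        np.testing.assert_allclose(total, ols, atol=1e-6)

    def test_matches_statsmodels_mixedlm_oracle(self, rng):
        """Independent-route check against statsmodels (no replicate term)."""
        import statsmodels.formula.api as smf

        table, _ = small_table(rng, n_populations=15, n_individuals=8,
                               sd_slope=0.5, corr_intercept_slope=0.3,
                               sd_replicate=0.0)
        X = np.column_stack([np.ones(len(table)), table["temp_scaled"]])
        mine = fit_lmm_gaussian(table["value"].to_numpy(), X,
                                table["population"].to_numpy(),
                                table["temp_scaled"].to_numpy(), rep=None)
        ref = smf.mixedlm("value ~ temp_scaled", table,
                          groups=table["population"],
                          re_formula="~temp_scaled").fit(reml=False)
        assert mine.loglik == pytest.approx(ref.llf, abs=1e-3)
        np.testing.assert_allclose(mine.beta, ref.fe_params.values, atol=1e-5)
        cov_re = ref.cov_re.values * ref.scale
        assert mine.sd_intercept == pytest.approx(np.sqrt(cov_re[0, 0]), rel=0.02)
        assert mine.sd_slope == pytest.approx(np.sqrt(cov_re[1, 1]), rel=0.05)
        assert mine.sigma_resid == pytest.approx(np.sqrt(ref.scale), rel=0.02)

    def test_parameter_recovery_short(self, rng):
        """Small-scale recovery run; the full 50-rep study is in acceptance."""
        corrs, sds = [], []
        for _ in range(5):
            table, truth = simulate_random_regression(
                rng, n_populations=20, sd_slope=0.3, sigma_resid=1.0)
            fit = fit_random_regression(table, "gaussian")
            est = fit.fixed_slope_scaled + fit.model.ranef["slope_dev"].to_numpy()
            corrs.append(np.corrcoef(truth["true_slope"], est)[0, 1])
            sds.append(fit.model.sd_slope)
        assert np.mean(corrs) >= 0.8
        assert 0.15 <= np.mean(sds) <= 0.45

    def test_population_slope_deviations_average_zero(self, rng):
        table, _ = small_table(rng, sd_slope=0.4)
        fit = fit_random_regression(table, "gaussian")
        assert abs(fit.model.ranef["slope_dev"].mean()) < 1e-6

    def test_deviations_shrink_as_residual_noise_grows(self, rng):
        # shrinkage of the conditional modes at fixed random-effect
        # covariance: raising sigma_resid (theta is relative to sigma, so
        # scaling theta down) pulls every deviation toward zero
        table, _ = small_table(rng, sd_slope=0.3, sigma_resid=1.0)
        X = np.column_stack([np.ones(len(table)), table["temp_scaled"]])
        args = (table["value"].to_numpy(), X, table["population"].to_numpy(),
                table["temp_scaled"].to_numpy(), table["replicate"].to_numpy())
        base = fit_lmm_gaussian(*args).theta
        spreads = []
        for scale in (1.0, 0.5, 0.25):  # sigma_resid x1, x2, x4
            fit = fit_lmm_gaussian(*args, theta_fixed=base * scale)
            spreads.append(np.abs(fit.ranef["slope_dev"]).mean())
        assert spreads[0] > spreads[1] > spreads[2]

    def test_plasticity_invariant_to_temperature_sign_flip(self, rng):
        table, _ = small_table(rng, sd_slope=0.4)
        fit1 = fit_random_regression(table, "gaussian")
        flipped = table.assign(temp_scaled=-table["temp_scaled"],
                               treatment_C=-table["treatment_C"])
        fit2 = fit_random_regression(flipped, "gaussian")
        p1 = extract_population_plasticity(fit1)["plasticity"].to_numpy()
        p2 = extract_population_plasticity(fit2)["plasticity"].to_numpy()
        np.testing.assert_allclose(np.sort(p1), np.sort(p2), rtol=1e-4)


class TestBinomialFit:
    def test_fixed_effects_recovered_within_three_se(self, rng):
        # eta = 1.0 - 0.3 * t_scaled, 25 seeds/dish, 16 dishes per population
        table, _ = simulate_random_regression(
            rng, n_populations=20, fixed_intercept=1.0, fixed_slope=-0.3,
            sd_intercept=0.5, sd_slope=0.2, sd_replicate=0.1,
            family="binomial", seeds_per_dish=25, dishes_per_cell=2)
        fit = fit_random_regression(table, "binomial")
        z = (fit.model.beta - np.array([1.0, -0.3])) / fit.model.se_beta
        assert np.all(np.abs(z) < 3.0)

    def test_aic_penalty_bounds_nested_models(self, rng):
        # log-likelihood dominance: richer model's AIC exceeds the nested
        # model's by at most twice the extra parameter count
        table, _ = simulate_random_regression(
            rng, n_populations=10, fixed_intercept=0.5, fixed_slope=-0.2,
            sd_slope=0.0, family="binomial")
        full = fit_random_regression(table, "binomial", random_slope=True)
        null = fit_random_regression(table, "binomial", random_slope=False)
        extra = full.model.n_params - null.model.n_params
        assert full.aic <= null.aic + 2 * extra + 1e-6


class TestRandomSlopeSupport:
    def test_delta_aic_definition(self, rng):
        table, _ = small_table(rng, sd_slope=1.0, sigma_resid=0.5)
        full = fit_random_regression(table, "gaussian", random_slope=True)
        null = fit_random_regression(table, "gaussian", random_slope=False)
        delta, supported = compare_random_slope_support(table, "gaussian")
        assert delta == pytest.approx(null.aic - full.aic, abs=1e-6)
        assert supported  # strong simulated slope variance

    def test_no_support_without_slope_variance(self, rng):
        table, _ = small_table(rng, sd_slope=0.0, sigma_resid=1.0)
        delta, _ = compare_random_slope_support(table, "gaussian")
        assert delta < 4.0  # no real signal: close to (or below) zero


class TestPlasticityExtraction:
    def _fit(self, rng, **kw):
        table, truth = small_table(rng, **kw)
        return fit_random_regression(table, "gaussian"), truth

    def test_absolute_value_arithmetic(self):
        assert abs(-0.5 + 0.2) == pytest.approx(0.3)  # fixed -0.5, dev +0.2
        # via the real pipeline objects:
        ranef = pd.DataFrame({"population": ["a"], "intercept_dev": [0.0],
                              "slope_dev": [0.2]})
        from thermoplast.mixed import MixedModelResult

        m = MixedModelResult(
            family="gaussian", random_slope=True, beta=np.array([0.0, -0.5]),
            cov_beta=np.eye(2), sd_intercept=1.0, sd_slope=0.2,
            corr_intercept_slope=0.0, sd_replicate=0.0, sigma_resid=1.0,
            loglik=0.0, aic=0.0, n_obs=8, n_params=5, converged=True,
            boundary=False, populations=["a"], ranef=ranef,
            ranef_replicate=pd.DataFrame(), theta=np.zeros(3))
        fit = ReactionNormFit("sp", "plant_height", "gaussian", m, 22.0, 1.0)
        rec = extract_population_plasticity(fit)
        assert rec.loc[0, "slope_per_C"] == pytest.approx(-0.3)
        assert rec.loc[0, "plasticity"] == pytest.approx(0.3)

    def test_back_transform_divides_by_temperature_sd(self, rng):
        # slope -2.902 per scaled unit with SD 5.164 C -> -0.562 per C
        assert -2.902 / 5.164 == pytest.approx(-0.562, abs=5e-4)
        fit, _ = self._fit(rng, sd_slope=0.3)
        rec = extract_population_plasticity(fit)
        scaled = fit.fixed_slope_scaled + fit.model.ranef["slope_dev"]
        np.testing.assert_allclose(rec["slope_per_C"],
                                   scaled / fit.temp_sd_C, atol=1e-12)

    def test_boundary_fit_gives_uniform_plasticity(self):
        t = np.tile(TEMPS, 24)
        pop = np.repeat([f"p{i}" for i in range(6)], 16)
        rng = np.random.default_rng(0)
        y = 1.0 - 0.4 * t + rng.normal(0, 0.5, t.size)  # no slope variance
        table = pd.DataFrame({"population": pop, "temp_scaled": t,
                              "value": y, "treatment_C": 22 + 5.164 * t})
        fit = fit_random_regression(table, "gaussian")
        rec = extract_population_plasticity(fit)
        if fit.model.boundary:
            assert rec["plasticity"].std() < 0.02


class TestLogitConversion:
    def test_reported_germination_decline(self):
        # printed logit intercept 1.307 and slope -0.078 per degree C
        pp = logit_slope_to_percentage_points(1.307, -0.078)
        assert pp < 0
        assert round(abs(pp), 1) == 1.3

    def test_zero_slope_gives_zero(self):
        assert logit_slope_to_percentage_points(0.0, 0.0) == 0.0

    def test_agrees_with_derivative_form(self):
        # p(1-p)*beta at eta0=0 is 0.025 -> +2.5 percentage points
        pp = logit_slope_to_percentage_points(0.0, 0.1)
        assert pp == pytest.approx(2.5, abs=0.05)
        assert round(pp, 1) == 2.5


class TestPredictions:
    def test_gaussian_prediction_line(self, rng):
        table, _ = small_table(rng, sd_slope=0.3)
        fit = fit_random_regression(table, "gaussian")
        temps = np.unique(table["treatment_C"])
        pred = predict_reaction_norms(fit, temps)
        # predictions equal the fitted linear predictor re-evaluated there
        for rec in fit.model.ranef.itertuples(index=False):
            sub = pred[pred["population"] == rec.population]
            t_scaled = (temps - fit.temp_mean_C) / fit.temp_sd_C
            eta = (fit.model.beta[0] + rec.intercept_dev
                   + (fit.model.beta[1] + rec.slope_dev) * t_scaled)
            np.testing.assert_allclose(sub["predicted"].to_numpy(), eta,
                                       atol=1e-12)
        assert (pred["ci_low"] <= pred["predicted"]).all()
        assert (pred["predicted"] <= pred["ci_high"]).all()

    def test_binomial_probability_bounds_and_midpoint(self, rng):
        table, _ = simulate_random_regression(
            rng, n_populations=8, fixed_intercept=0.0, fixed_slope=-0.5,
            sd_intercept=0.3, sd_slope=0.1, family="binomial")
        fit = fit_random_regression(table, "binomial")
        pred = predict_reaction_norms(fit, np.array([22.0]))
        assert ((pred[["predicted", "ci_low", "ci_high"]] > 0).all().all()
                and (pred[["predicted", "ci_low", "ci_high"]] < 1).all().all())

    def test_far_extrapolation_warns(self, rng):
        table, _ = small_table(rng)
        fit = fit_random_regression(table, "gaussian")
        with pytest.warns(UserWarning, match="outside"):
            predict_reaction_norms(fit, np.array([80.0]))
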