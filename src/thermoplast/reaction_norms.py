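"""Thermal reaction norms and population-level plasticity.

Each species x trait combination is modelled as a linear reaction norm over
temperature: a fixed intercept and slope on the z-scored temperature axis,
correlated population-specific random deviations in both (a random
regression), and a random intercept for the experimental replicate.
Gaussian traits use an identity link; germination uses a binomial-logit
model on (germinated, viable) seed counts per dish.

The magnitude of a population's plastic response — its *plasticity* — is the
absolute value of its total slope (fixed + population deviation),
back-transformed from scaled-temperature units to per-degree-Celsius units
by dividing by the temperature SD. Statistical support for among-population
variation in slopes is assessed by the AIC difference between the
random-intercept-only model and the random-intercept-plus-slope model;
a difference above 2 counts as support for the random-slope component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .mixed import MixedModelResult, fit_glmm_binomial, fit_lmm_gaussian

__all__ = [
    "ReactionNormFit",
    "fit_random_regression",
    "compare_random_slope_support",
    "extract_population_plasticity",
    "logit_slope_to_percentage_points",
    "predict_reaction_norms",
    "DELTA_AIC_SUPPORT",
]

DELTA_AIC_SUPPORT = 2.0


@dataclass
class ReactionNormFit:
    """Random-regression fit for one species x trait combination."""

    species: str
    trait: str
    family: str
    model: MixedModelResult
    temp_mean_C: float
    temp_sd_C: float

    @property
    def fixed_intercept(self) -> float:
        return float(self.model.beta[0])

    @property
    def fixed_slope_scaled(self) -> float:
        """Fixed slope per scaled-temperature unit."""
        return float(self.model.beta[1])

    @property
    def fixed_slope_per_C(self) -> float:
        return self.fixed_slope_scaled / self.temp_sd_C

    @property
    def sd_slope_per_C(self) -> float:
        return self.model.sd_slope / self.temp_sd_C

    @property
    def aic(self) -> float:
        return self.model.aic


def _validate_table(table: pd.DataFrame, family: str) -> None:
    need = {"population", "temp_scaled"}
    if family == "binomial":
        need |= {"n_germinated", "n_viable"}
    else:
        need |= {"value"}
    missing = need - set(table.columns)
    if missing:
        raise ValueError(f"trait table is missing columns: {sorted(missing)}")
    if table["population"].nunique() < 2:
        raise ValueError("random regression needs at least 2 populations")
    if table["temp_scaled"].nunique() < 2:
        raise ValueError("random regression needs at least 2 distinct temperatures")


def fit_random_regression(
    table: pd.DataFrame, family: str = "gaussian", random_slope: bool = True,
    species: str = "", trait: str = "",
) -> ReactionNormFit:
    """Fit the random-regression model for one species x trait table.

    ``table`` must carry ``population``, ``temp_scaled`` and either
    ``value`` (Gaussian) or ``n_germinated``/``n_viable`` (binomial);
    ``replicate`` and ``treatment_C`` are used when present.
    """
    _validate_table(table, family)
    t = table["temp_scaled"].to_numpy(float)
    X = np.column_stack([np.ones(len(table)), t])
    popv = table["population"].to_numpy()
    rep = table["replicate"].to_numpy() if "replicate" in table.columns else None
    if rep is not None and len(np.unique(rep)) < 2:
        rep = None

    if family == "gaussian":
        fit = fit_lmm_gaussian(table["value"].to_numpy(float), X, popv, t,
                               rep=rep, random_slope=random_slope)
    elif family == "binomial":
        fit = fit_glmm_binomial(table["n_germinated"].to_numpy(float),
                                table["n_viable"].to_numpy(float), X, popv, t,
                                rep=rep, random_slope=random_slope)
    else:
        raise ValueError(f"unknown family {family!r}")
    if not fit.converged:
        raise RuntimeError(
            f"random-regression fit did not converge (family={family}, "
            f"n_obs={fit.n_obs}, theta={fit.theta})"
        )

    if "treatment_C" in table.columns:
        temp_mean = float(table["treatment_C"].mean())
        temp_sd = float(table["treatment_C"].std(ddof=1))
    else:  # already-scaled input: per-degree equals per-scaled-unit
        temp_mean, temp_sd = 0.0, 1.0
    return ReactionNormFit(species=species, trait=trait, family=family,
                           model=fit, temp_mean_C=temp_mean, temp_sd_C=temp_sd)


def compare_random_slope_support(
    table: pd.DataFrame, family: str = "gaussian", species: str = "",
    trait: str = "",
) -> tuple[float, bool]:
    """AIC support for population-specific slopes.

    Returns ``(delta_aic, supported)`` with
    ``delta_aic = AIC(random intercept only) - AIC(random intercept + slope)``;
    values above 2 are treated as support for the random-slope component.
    """
    full = fit_random_regression(table, family, random_slope=True,
                                 species=species, trait=trait)
    null = fit_random_regression(table, family, random_slope=False,
                                 species=species, trait=trait)
    delta = null.aic - full.aic
    return float(delta), bool(delta > DELTA_AIC_SUPPORT)


def extract_population_plasticity(fit: ReactionNormFit) -> pd.DataFrame:
    """Per-population total slope and plasticity, in units per degree C.

    Total slope = fixed slope + population slope deviation (conditional
    mode), divided by the temperature SD in degrees C to undo the z-scaling;
    plasticity is its absolute value.
    """
    ranef = fit.model.ranef
    total_scaled = fit.fixed_slope_scaled + ranef["slope_dev"].to_numpy()
    total_per_C = total_scaled / fit.temp_sd_C
    return pd.DataFrame(
        {
            "species": fit.species,
            "population": ranef["population"],
            "trait": fit.trait,
            "slope_per_C": total_per_C,
            "plasticity": np.abs(total_per_C),
        }
    )


def logit_slope_to_percentage_points(
    intercept_logit: float, slope_logit_per_C: float
) -> float:
    """Germination-probability change, in percentage points per +1 degree C.

    Evaluates the inverse logit at the fitted intercept and one slope-step
    below it: ``100 * [p(eta0) - p(eta0 - beta)]``. The sign of the slope is
    preserved (a negative slope gives a negative change).
    """
    eta0 = float(intercept_logit)
    beta = float(slope_logit_per_C)
    return 100.0 * (expit(eta0) - expit(eta0 - beta))


def predict_reaction_norms(
    fit: ReactionNormFit, temperatures_C: np.ndarray, level: float = 0.95,
) -> pd.DataFrame:
    """Per-population predictions on the response scale with CI bands.

    Bands come from the fixed-effect covariance on the link scale; for the
    binomial family the interval endpoints are mapped through the inverse
    logit so probabilities stay in (0, 1).
    """
    from scipy.stats import norm

    temps = np.asarray(temperatures_C, float)
    lo_t, hi_t = fit.temp_mean_C - 2.5 * fit.temp_sd_C, fit.temp_mean_C + 2.5 * fit.temp_sd_C
    if np.any((temps < lo_t) | (temps > hi_t)):
        warnings.warn("predicting far outside the fitted temperature range")
    t_scaled = (temps - fit.temp_mean_C) / fit.temp_sd_C
    z = norm.ppf(0.5 + level / 2.0)
    beta = fit.model.beta
    cov = fit.model.cov_beta

    rows = []
    for rec in fit.model.ranef.itertuples(index=False):
        eta = (beta[0] + rec.intercept_dev) + (beta[1] + rec.slope_dev) * t_scaled
        Xg = np.column_stack([np.ones_like(t_scaled), t_scaled])
        se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, cov, Xg))
        lo, hi = eta - z * se, eta + z * se
        if fit.family == "binomial":
            pred, lo, hi = expit(eta), expit(lo), expit(hi)
        else:
            pred = eta
        for T, pr, l, h in zip(temps, pred, lo, hi):
            rows.append({"population": rec.population, "treatment_C": T,
                         "predicted": pr, "ci_low": l, "ci_high": h})
    return pd.DataFrame(rows)
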