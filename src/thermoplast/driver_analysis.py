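"""Relating plasticity to range position and environmental heterogeneity.

For each trait, per-population plasticity is regressed on one range-position
metric (DRE or DCE) crossed with one heterogeneity metric (SHDI, PAR or
ARE), with and without their interaction — a grid of 2 x 3 x 2 = 12
candidate ordinary-least-squares models. Models are ranked by AIC; the
lowest-AIC model is selected and competitors within 2 AIC units are listed
as additionally supported. The selected model's explained variance is
partitioned over its terms by the LMG method: each regressor's share is its
sequential R-squared increment averaged over every ordering of the
regressors, so shares are non-negative and sum to the model R-squared.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import spearmanr

__all__ = [
    "ModelSpec",
    "CandidateModelFit",
    "RP_METRICS",
    "EH_METRICS",
    "assemble_driver_table",
    "enumerate_candidate_models",
    "fit_and_rank_models",
    "lmg_relative_importance",
    "correlation_screen",
    "report_results",
]

RP_METRICS = ("DRE", "DCE")
EH_METRICS = ("SHDI", "PAR", "ARE")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate driver model: an RP metric, an EH metric, +/- interaction."""

    rp: str
    eh: str
    interaction: bool

    @property
    def terms(self) -> list[str]:
        t = [self.eh, self.rp]
        if self.interaction:
            t.append(f"{self.eh}:{self.rp}")
        return t

    def __str__(self) -> str:
        return f"plasticity ~ {self.eh} {'*' if self.interaction else '+'} {self.rp}"


@dataclass
class CandidateModelFit:
    """Fitted candidate model with selection and importance summaries."""

    trait: str
    spec: ModelSpec
    coefficients: pd.DataFrame = field(repr=False)  # term, estimate, se, t, p, band
    aic: float
    delta_aic: float
    r_squared: float
    lmg_shares: dict[str, float] = field(default_factory=dict)
    unexplained: float = float("nan")
    n_obs: int = 0


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"cannot z-scale constant column {x.name!r}")
    return (x - x.mean()) / sd


def assemble_driver_table(
    plasticity: pd.DataFrame, site_metrics: pd.DataFrame,
    metrics: tuple[str, ...] = RP_METRICS + EH_METRICS,
) -> pd.DataFrame:
    """Join per-population plasticity with freshly z-scaled site metrics.

    ``plasticity`` needs ``population`` and ``plasticity`` columns (one row
    per population for a single trait); ``site_metrics`` needs
    ``population`` plus the metric columns (``DRE`` may be supplied as
    ``DRE_km``). Scaling is recomputed on exactly the joined rows, so means
    stay at zero after any row exclusion.
    """
    sm_ = site_metrics.rename(columns={"DRE_km": "DRE"}).copy()
    missing_m = [m for m in metrics if m not in sm_.columns]
    if missing_m:
        raise ValueError(f"site metrics are missing columns: {missing_m}")
    unmatched = sorted(set(plasticity["population"]) - set(sm_["population"]))
    if unmatched:
        raise ValueError(f"populations without site metrics: {unmatched}")
    na_rows = sm_[sm_["population"].isin(plasticity["population"])]
    bad = na_rows[na_rows[list(metrics)].isna().any(axis=1)]["population"].tolist()
    if bad:
        raise ValueError(f"populations with missing metric values: {bad}")
    if plasticity["plasticity"].isna().any():
        raise ValueError("plasticity table contains missing values")

    keep = ["population"] + list(metrics)
    table = plasticity.merge(sm_[keep], on="population", how="left")
    for m in metrics:
        table[m] = _zscore(table[m])
    return table


def enumerate_candidate_models(
    rp_set: tuple[str, ...] = RP_METRICS, eh_set: tuple[str, ...] = EH_METRICS,
) -> list[ModelSpec]:
    """Cartesian grid of RP x EH x {without, with interaction} model specs."""
    if not rp_set or not eh_set:
        raise ValueError("rp_set and eh_set must be non-empty")
    return [
        ModelSpec(rp=rp, eh=eh, interaction=inter)
        for rp in rp_set
        for eh in eh_set
        for inter in (False, True)
    ]


def _design_matrix(table: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    cols = [table[spec.eh].to_numpy(float), table[spec.rp].to_numpy(float)]
    names = [spec.eh, spec.rp]
    if spec.interaction:
        cols.append(cols[0] * cols[1])
        names.append(f"{spec.eh}:{spec.rp}")
    X = np.column_stack([np.ones(len(table))] + cols)
    return X, ["Intercept"] + names


def _ols_aic(res) -> float:
    """Gaussian AIC with k = number of coefficients + 1 (residual variance)."""
    k = res.df_model + 1 + 1  # slopes + intercept + sigma^2
    return float(-2.0 * res.llf + 2.0 * k)


def _p_band(p: float) -> str:
    if p < 0.01:
        return "<0.01"
    if p < 0.05:
        return "<0.05"
    if p < 0.1:
        return "<0.1"
    return "ns"


def fit_and_rank_models(
    table: pd.DataFrame, specs: list[ModelSpec] | None = None,
    trait: str = "", response: str = "plasticity",
    delta_aic_threshold: float = 2.0,
) -> list[CandidateModelFit]:
    """Fit every candidate model by OLS and rank by AIC.

    Returns fits sorted by AIC (best first) with ``delta_aic`` relative to
    the best; the best model carries LMG shares. Models within
    ``delta_aic_threshold`` of the best are the "additionally supported"
    competitors.
    """
    if specs is None:
        specs = enumerate_candidate_models()
    y = table[response].to_numpy(float)
    max_par = max(len(s.terms) for s in specs) + 1
    if len(table) <= max_par:
        raise ValueError("too few populations for the candidate models")
    if np.ptp(y) == 0:
        raise ValueError(
            f"response {response!r} has zero variance across populations; "
            "driver models are undefined (random-slope variance likely "
            "estimated at the boundary upstream)"
        )

    fits = []
    for spec in specs:
        X, names = _design_matrix(table, spec)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient design for {spec}: columns {names}")
        res = sm.OLS(y, X).fit()
        coef = pd.DataFrame({
            "term": names,
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        })
        coef["band"] = [_p_band(p) for p in coef["p"]]
        fits.append(CandidateModelFit(
            trait=trait, spec=spec, coefficients=coef, aic=_ols_aic(res),
            delta_aic=np.nan, r_squared=float(res.rsquared), n_obs=len(table),
        ))
    best_aic = min(f.aic for f in fits)
    for f in fits:
        f.delta_aic = f.aic - best_aic
    fits.sort(key=lambda f: (f.aic, len(f.spec.terms)))
    best = fits[0]
    reg = {}
    for term in best.spec.terms:
        if ":" in term:
            a, b = term.split(":")
            reg[term] = table[a].to_numpy(float) * table[b].to_numpy(float)
        else:
            reg[term] = table[term].to_numpy(float)
    shares, unexplained = lmg_relative_importance(pd.DataFrame(reg), y)
    best.lmg_shares, best.unexplained = shares, unexplained
    return fits


def lmg_relative_importance(
    regressors: pd.DataFrame, y: np.ndarray
) -> tuple[dict[str, float], float]:
    """LMG variance decomposition of an OLS fit.

    Each regressor column (interaction columns included, treated as
    ordinary regressors) receives the average over all orderings of its
    sequential increment to R-squared. Shares sum to the full-model
    R-squared; the returned ``unexplained`` is ``1 - R**2``.
    """
    names = list(regressors.columns)
    t = len(names)
    if t < 1:
        raise ValueError("need at least one regressor")
    if t > 10:
        raise ValueError(
            "LMG over more than 10 regressors is a factorial blow-up; "
            "reduce the model or use a sampling approximation"
        )
    y = np.asarray(y, float)
    n = len(y)
    Xall = regressors.to_numpy(float)
    ones = np.ones((n, 1))
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("response has zero variance; R^2 shares are undefined")

    r2_cache: dict[frozenset, float] = {frozenset(): 0.0}

    def r2(subset: frozenset) -> float:
        if subset not in r2_cache:
            X = np.hstack([ones, Xall[:, sorted(subset)]])
            resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            r2_cache[subset] = 1.0 - float((resid**2).sum()) / tss
        return r2_cache[subset]

    # subset-weighted form of the all-orderings average
    shares = {}
    for j in range(t):
        others = [i for i in range(t) if i != j]
        total = 0.0
        for size in range(t):
            w = math.factorial(size) * math.factorial(t - size - 1) / math.factorial(t)
            for combo in itertools.combinations(others, size):
                s = frozenset(combo)
                total += w * (r2(s | {j}) - r2(s))
        shares[names[j]] = total
    full_r2 = r2(frozenset(range(t)))
    return shares, 1.0 - full_r2


def correlation_screen(
    site_metrics: pd.DataFrame, metrics: tuple[str, ...] = RP_METRICS + EH_METRICS,
    flag_threshold: float = 0.7,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Spearman rank correlations among the explanatory metrics.

    Returns the correlation matrix and the list of pairs with
    ``|rho| >= flag_threshold`` (candidates for problematic collinearity).
    """
    sm_ = site_metrics.rename(columns={"DRE_km": "DRE"})
    if len(sm_) < 3:
        raise ValueError("need at least 3 populations for a correlation screen")
    for m in metrics:
        if sm_[m].nunique() <= 1:
            raise ValueError(f"metric {m!r} is constant; correlations undefined")
    mat = np.eye(len(metrics))
    flags = []
    for i, a in enumerate(metrics):
        for j in range(i + 1, len(metrics)):
            b = metrics[j]
            rho = float(spearmanr(sm_[a], sm_[b]).statistic)
            mat[i, j] = mat[j, i] = rho
            if abs(rho) >= flag_threshold:
                flags.append((a, b, rho))
    return pd.DataFrame(mat, index=list(metrics), columns=list(metrics)), flags


def report_results(
    grid_fits: dict[str, list[CandidateModelFit]],
    plasticity: pd.DataFrame | None = None,
    norm_fits: list | None = None,
) -> dict[str, pd.DataFrame]:
    """Machine-readable result tables.

    * ``model_grid`` — per trait, the 12 candidate models with their
      delta-AIC (the selection grid).
    * ``selected_models`` — coefficient table of each trait's best model.
    * ``variance_partition`` — LMG shares of each best model plus the
      unexplained remainder (rows sum to one).
    * ``reaction_norm_summary`` — per species x trait fixed effects and the
      spread (SD/min/max) of per-population slopes, when plasticity records
      and reaction-norm fits are supplied.
    """
    grid_rows, sel_rows, var_rows = [], [], []
    for trait, fits in grid_fits.items():
        for f in fits:
            grid_rows.append({"trait": trait, "rp": f.spec.rp, "eh": f.spec.eh,
                              "interaction": f.spec.interaction,
                              "delta_aic": f.delta_aic, "aic": f.aic,
                              "r_squared": f.r_squared})
        best = min(fits, key=lambda f: f.aic)
        for rec in best.coefficients.itertuples(index=False):
            sel_rows.append({"trait": trait, "model": str(best.spec),
                             "term": rec.term, "estimate": rec.estimate,
                             "se": rec.se, "t": rec.t, "p": rec.p,
                             "band": rec.band})
        for term, share in best.lmg_shares.items():
            var_rows.append({"trait": trait, "component": term, "share": share})
        var_rows.append({"trait": trait, "component": "unexplained",
                         "share": best.unexplained})

    out = {
        "model_grid": pd.DataFrame(grid_rows),
        "selected_models": pd.DataFrame(sel_rows),
        "variance_partition": pd.DataFrame(var_rows),
    }
    if norm_fits:
        summ = []
        for fit, plast in norm_fits:
            slopes = plast["slope_per_C"].to_numpy()
            summ.append({
                "species": fit.species, "trait": fit.trait,
                "estimate_per_C": fit.fixed_slope_per_C,
                "se_per_C": float(fit.model.se_beta[1] / fit.temp_sd_C),
                "sd_pop": float(np.std(slopes, ddof=1)),
                "min_pop": float(slopes.min()), "max_pop": float(slopes.max()),
            })
        out["reaction_norm_summary"] = pd.DataFrame(summ)
    return out
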