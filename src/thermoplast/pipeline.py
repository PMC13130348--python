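"""End-to-end orchestration of the synthetic study and driver analysis."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, Polygon

from . import driver_analysis, heterogeneity, range_position, reaction_norms
from .rasters import write_ascii_grid
from .synthetic_data import SyntheticConfig, simulate_study
from .trait_prep import GAUSSIAN_TRAITS, prepare_trait_table

__all__ = ["run_synthetic_study", "write_study", "analyze_drivers"]


def run_synthetic_study(config: SyntheticConfig) -> dict:
    """Simulate a study and push it through the full analysis chain.

    Returns a dict with the simulated artifacts plus, per species:
    site metrics (DRE/DCE/SHDI/PAR/ARE), reaction-norm fits, plasticity
    records, and the pooled driver-model results per trait.
    """
    study = simulate_study(config)
    trait_table = prepare_trait_table(study["trait_table"])

    all_metrics, all_plast = [], []
    norm_fits = []
    for sp, art in study["species"].items():
        sites = art["sites"]
        rpdf = range_position.site_range_position(
            sites, art["range_map"].boundary, art["climate"],
            _site_climate(art, sites),
        )
        het_rows = []
        for rec in sites.itertuples(index=False):
            lc, dem = art["landscapes"][rec.population]
            het_rows.append(heterogeneity.site_heterogeneity(
                lc, dem, (0.0, 0.0), site_id=str(rec.population)))
        metrics = rpdf.merge(pd.DataFrame(het_rows), on="population")
        metrics.insert(0, "species", sp)
        all_metrics.append(metrics)

        for trait in set(trait_table.loc[trait_table["species"] == sp, "trait"]):
            sub = trait_table[(trait_table["species"] == sp)
                              & (trait_table["trait"] == trait)]
            family = "gaussian" if trait in GAUSSIAN_TRAITS else "binomial"
            fit = reaction_norms.fit_random_regression(
                sub, family=family, species=sp, trait=trait)
            plast = reaction_norms.extract_population_plasticity(fit)
            norm_fits.append((fit, plast))
            all_plast.append(plast)

    metrics = pd.concat(all_metrics, ignore_index=True)
    plasticity = pd.concat(all_plast, ignore_index=True)

    grid_fits = {}
    for trait in sorted(plasticity["trait"].unique()):
        ptab = plasticity[plasticity["trait"] == trait]
        merged_key = ["species", "population"]
        joined = ptab.merge(metrics, on=merged_key)
        joined = joined.assign(population=joined["species"] + ":" + joined["population"])
        table = driver_analysis.assemble_driver_table(
            joined[["population", "plasticity"]],
            joined[["population", "DRE_km", "DCE", "SHDI", "PAR", "ARE"]],
        )
        grid_fits[trait] = driver_analysis.fit_and_rank_models(table, trait=trait)

    report = driver_analysis.report_results(grid_fits, plasticity, norm_fits)
    return {"study": study, "trait_table": trait_table, "metrics": metrics,
            "plasticity": plasticity, "grid_fits": grid_fits, "report": report}


def _site_climate(art: dict, sites: pd.DataFrame) -> pd.DataFrame:
    """Climate at each site = nearest range-cell climate."""
    clim = art["climate"]
    cells = clim[["x", "y"]].to_numpy()
    vars_ = [c for c in clim.columns if c.startswith("bio")]
    rows = []
    for rec in sites.itertuples(index=False):
        d2 = ((cells - np.array([rec.x, rec.y])) ** 2).sum(axis=1)
        rows.append(clim.iloc[int(np.argmin(d2))][vars_])
    return pd.DataFrame(rows).reset_index(drop=True)


def write_study(result: dict, out_dir: str | Path) -> None:
    """Write simulated artifacts as plain-text files (CSV/GeoJSON/ASCII grid)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result["trait_table"].to_csv(out / "traits.csv", index=False)
    result["metrics"].to_csv(out / "site_metrics.csv", index=False)
    result["plasticity"].to_csv(out / "plasticity.csv", index=False)
    for name, df in result["report"].items():
        df.to_csv(out / f"{name}.csv", index=False)
    for sp, art in result["study"]["species"].items():
        spdir = out / sp
        spdir.mkdir(exist_ok=True)
        geo = {"type": "Feature", "properties": {"species": sp},
               "geometry": mapping(Polygon(art["range_map"].boundary))}
        (spdir / "range.geojson").write_text(json.dumps(geo))
        art["climate"].to_csv(spdir / "climate.csv", index=False)
        art["sites"].to_csv(spdir / "sites.csv", index=False)
        for popname, (lc, dem) in art["landscapes"].items():
            write_ascii_grid(lc, spdir / f"{popname}_landcover.asc")
            write_ascii_grid(dem, spdir / f"{popname}_elevation.asc")
        truth = result["study"]["truth"][sp]["gaussian"].populations
        truth.to_csv(spdir / "truth.csv", index=False)


def analyze_drivers(
    plasticity: pd.DataFrame, metrics: pd.DataFrame, out_dir: str | Path,
    delta_aic_threshold: float = 2.0,
) -> dict[str, pd.DataFrame]:
    """Driver-model grid + report from plasticity and site-metric tables."""
    grid_fits = {}
    for trait in sorted(plasticity["trait"].unique()):
        ptab = plasticity[plasticity["trait"] == trait]
        table = driver_analysis.assemble_driver_table(
            ptab[["population", "plasticity"]], metrics)
        grid_fits[trait] = driver_analysis.fit_and_rank_models(
            table, trait=trait, delta_aic_threshold=delta_aic_threshold)
    report = driver_analysis.report_results(grid_fits)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in report.items():
        df.to_csv(out / f"{name}.csv", index=False)
    sel = {
        trait: {"model": str(min(fits, key=lambda f: f.aic).spec),
                "aic": min(f.aic for f in fits),
                "supported_competitors": [
                    str(f.spec) for f in fits
                    if 0 < f.delta_aic <= delta_aic_threshold
                ]}
        for trait, fits in grid_fits.items()
    }
    (out / "selected_models.json").write_text(json.dumps(sel, indent=2))
    return report
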