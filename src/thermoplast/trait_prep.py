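"""Turn raw germination and greenhouse records into the five analysis traits.

Traits: germination probability (proportion of viable seeds that
germinated), germination phenology (days from sowing to germination),
flowering phenology (days from sowing to first flower), plant height (cm)
and flower abundance (flower count, square-root-transformed for analysis).

Viability comes from end-of-experiment cut tests: seeds scored as
germinated, full or moldy count as viable; empty and infested seeds do not.
Populations whose pooled germination proportion is not strictly above 5% of
viable seeds are excluded (low germination there most likely reflects
incomplete dormancy release rather than a thermal response).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "TRAITS",
    "GAUSSIAN_TRAITS",
    "count_viable_seeds",
    "germination_metrics",
    "apply_germination_filter",
    "prepare_trait_table",
]

TRAITS = (
    "germination_probability",
    "germination_phenology",
    "flowering_phenology",
    "plant_height",
    "flower_abundance",
)
GAUSSIAN_TRAITS = TRAITS[1:]

_CUT_CATEGORIES = ("germinated", "full", "empty", "moldy", "infested")
_CENSUS_DAYS = (7, 14, 21, 28)  # weekly checks over the 4-week monitoring period


def count_viable_seeds(record: pd.Series | dict) -> int:
    """Viable seeds on one dish: total sown minus empty and infested.

    Germinated, full and moldy seeds all count as viable.
    """
    counts = {c: int(record[c]) for c in _CUT_CATEGORIES}
    if any(v < 0 for v in counts.values()):
        raise ValueError("cut-test counts must be non-negative")
    total = sum(counts.values())
    return total - counts["empty"] - counts["infested"]


def germination_metrics(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-dish germination proportion and per-seed phenology rows.

    ``records`` has one row per dish with the cut-test category counts and,
    optionally, weekly germination counts ``germinated_week1..4``. When the
    weekly columns are present their sum must equal ``germinated`` and each
    germinating seed yields a phenology row at the census day (7/14/21/28
    days after sowing). Dishes with zero viable seeds raise an error, since
    their proportion is undefined.
    """
    week_cols = [f"germinated_week{w}" for w in range(1, 5)]
    have_weeks = all(c in records.columns for c in week_cols)
    props, phen = [], []
    for _, row in records.iterrows():
        viable = count_viable_seeds(row)
        if viable == 0:
            raise ValueError(
                f"dish {row.get('dish', '?')} of population "
                f"{row.get('population', '?')} has no viable seeds; "
                "germination proportion undefined"
            )
        germinated = int(row["germinated"])
        if have_weeks:
            weekly = [int(row[c]) for c in week_cols]
            if sum(weekly) != germinated:
                raise ValueError("weekly germination counts do not sum to total")
            for day, cnt in zip(_CENSUS_DAYS, weekly):
                for _ in range(cnt):
                    phen.append({"population": row.get("population"),
                                 "dish": row.get("dish"), "days_to_germination": day})
        props.append({"population": row.get("population"), "dish": row.get("dish"),
                      "n_viable": viable, "n_germinated": germinated,
                      "proportion": germinated / viable})
    return pd.DataFrame(props), pd.DataFrame(phen)


def apply_germination_filter(
    summaries: pd.DataFrame, threshold: float = 0.05
) -> pd.DataFrame:
    """Flag populations whose pooled germination exceeds the threshold.

    Pooled = sum(germinated) / sum(viable) across a population's dishes;
    inclusion requires the proportion to be *strictly* greater than the
    threshold (a population at exactly 5% is excluded).
    """
    pooled = (
        summaries.groupby("population", as_index=False)[["n_germinated", "n_viable"]]
        .sum()
    )
    pooled["pooled_proportion"] = pooled["n_germinated"] / pooled["n_viable"]
    pooled["included"] = pooled["pooled_proportion"] > threshold
    return pooled


def prepare_trait_table(observations: pd.DataFrame) -> pd.DataFrame:
    """Apply analysis transforms and add the scaled-temperature column.

    Flower-abundance values are replaced by their square root. Temperature
    is z-scored (sample SD, over observation rows) separately within each
    species x trait combination — the grouping at which reaction norms are
    fitted — and the raw Celsius column is retained so slopes can be
    back-transformed to per-degree units.
    """
    obs = observations.copy()
    need = {"species", "population", "treatment_C", "trait", "value"}
    missing = need - set(obs.columns)
    if missing:
        raise ValueError(f"observations are missing columns: {sorted(missing)}")

    fa = obs["trait"] == "flower_abundance"
    if (obs.loc[fa, "value"] < 0).any():
        raise ValueError("flower abundance contains negative counts")
    obs.loc[fa, "value"] = np.sqrt(obs.loc[fa, "value"].astype(float))

    def _scale(temp: pd.Series) -> pd.Series:
        sd = temp.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("cannot scale temperature: fewer than 2 distinct values")
        return (temp - temp.mean()) / sd

    obs["temp_scaled"] = (
        obs.groupby(["species", "trait"])["treatment_C"].transform(_scale)
    )
    return obs
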