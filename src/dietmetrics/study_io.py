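"""Study data model, file readers, and the food -> group -> nutrient aggregation layer.

The pipeline's bulk containers are pandas DataFrames with fixed column schemas
(documented in the ``*_COLUMNS`` constants).  Lightweight dataclasses are
provided for single records where a typed row is more convenient than a frame.

File dialect: UTF-8, comma-delimited with a header row; tab is accepted via the
``sep`` argument.  Malformed rows are never silently dropped — they are routed
to a rejection report carrying the 1-based line number of the offending row.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("dietmetrics")

INSTRUMENTS = ("app", "recall24", "ffq")

CONSUMPTION_COLUMNS = ["participant_id", "instrument", "day_index", "food_id", "grams"]
GROUP_INTAKE_COLUMNS = ["participant_id", "instrument", "group_id", "grams"]

#: Covariates used in all adjusted models (the study's adjustment set).
COVARIATE_COLUMNS = [
    "age_y", "sex", "education", "met_min_wk", "smoker", "psqi_score", "study_group",
]

#: Soft physiological plausibility ranges; violations warn, never error.
PROFILE_RANGES = {
    "age_y": (18, 90),
    "height_cm": (100, 220),
    "weight_kg": (25, 250),
    "wc_cm": (40, 200),
    "muac_cm": (10, 60),
    "sbp_mmHg": (60, 260),
    "dbp_mmHg": (30, 160),
    "hb_gL": (40, 220),
    "fpg_mgdL": (30, 600),
    "hba1c_pct": (3, 20),
}


class SchemaError(ValueError):
    """A required column is missing or a table violates its schema."""


@dataclass(frozen=True)
class FoodItem:
    """One food in the catalog: identity, GDQS group membership, composition per 100 g."""

    food_id: str
    name: str
    group_id: str
    per100g: Mapping[str, float]

    def __post_init__(self):
        bad = {k: v for k, v in self.per100g.items() if np.isfinite(v) and v < 0}
        if bad:
            raise ValueError(f"negative composition values for {self.food_id}: {bad}")


@dataclass(frozen=True)
class ConsumptionRecord:
    """One food eaten by one participant on one day via one instrument, in grams."""

    participant_id: str
    instrument: str
    day_index: int
    food_id: str
    grams: float

    def __post_init__(self):
        if self.instrument not in INSTRUMENTS:
            raise ValueError(f"unknown instrument {self.instrument!r}")
        if not np.isfinite(self.grams) or self.grams < 0:
            raise ValueError(f"grams must be finite and >= 0, got {self.grams}")


@dataclass
class StudyTables:
    """The three study tables plus the rejection report from loading."""

    foods: pd.DataFrame          # indexed by food_id: name, group_id, nutrient columns
    consumption: pd.DataFrame    # CONSUMPTION_COLUMNS
    profiles: pd.DataFrame       # one row per participant
    rejects: pd.DataFrame        # line, reason + raw row fields


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def load_food_catalog(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Load foods.csv: food_id,name,group_id,<nutrient columns per 100 g>.

    Returns a frame indexed by food_id. Nutrient columns are float; negative
    values raise, missing values stay NaN (meaning "not measured").
    """
    df = pd.read_csv(path, sep=sep, dtype={"food_id": str, "name": str, "group_id": str})
    for col in ("food_id", "name", "group_id"):
        if col not in df.columns:
            raise SchemaError(f"foods table missing required column {col!r}")
    nutrient_cols = [c for c in df.columns if c not in ("food_id", "name", "group_id")]
    df[nutrient_cols] = df[nutrient_cols].astype(float)
    neg = (df[nutrient_cols] < 0).any(axis=None)
    if neg:
        raise SchemaError("foods table contains negative per-100 g values")
    if df["food_id"].duplicated().any():
        dupes = df.loc[df["food_id"].duplicated(), "food_id"].tolist()
        raise SchemaError(f"duplicate food_id values: {dupes}")
    return df.set_index("food_id")


def load_consumption(
    path: str | Path,
    catalog: pd.DataFrame | None = None,
    sep: str = ",",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load consumption.csv, validating row by row.

    Returns ``(records, rejects)``.  Rejected rows (non-numeric or negative
    grams, unknown instrument, bad day index, food_id absent from *catalog*)
    carry their 1-based file line number and a reason.  Valid duplicate keys
    are aggregated by summing grams so (participant, instrument, day, food)
    is unique in the output.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in CONSUMPTION_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"consumption table missing required column {col!r}")
    # line 1 is the header -> first data row is file line 2
    raw = raw.copy()
    raw["line"] = np.arange(2, len(raw) + 2)

    grams = pd.to_numeric(raw["grams"], errors="coerce")
    day = pd.to_numeric(raw["day_index"], errors="coerce")

    reasons = pd.Series("", index=raw.index, dtype=object)
    bad_grams = grams.isna() | ~np.isfinite(grams.fillna(np.nan)) | (grams < 0)
    reasons[bad_grams] = "non-numeric, non-finite, or negative grams"
    bad_instr = ~raw["instrument"].isin(INSTRUMENTS)
    reasons[bad_instr & (reasons == "")] = "unknown instrument"
    bad_day = day.isna() | (day != day.round()) | (day < 0)
    reasons[bad_day & (reasons == "")] = "day_index not a nonnegative integer"
    if catalog is not None:
        unknown = ~raw["food_id"].isin(catalog.index)
        reasons[unknown & (reasons == "")] = "food_id not in catalog"

    ok = reasons == ""
    rejects = raw.loc[~ok, ["line"] + CONSUMPTION_COLUMNS].copy()
    rejects.insert(1, "reason", reasons[~ok])

    records = raw.loc[ok, ["participant_id", "instrument", "food_id"]].copy()
    records["day_index"] = day[ok].astype(int)
    records["grams"] = grams[ok].astype(float)
    records = (
        records.groupby(["participant_id", "instrument", "day_index", "food_id"],
                        as_index=False, sort=False)["grams"].sum()
    )
    n_in, n_keep, n_rej = len(raw), ok.sum(), (~ok).sum()
    if n_keep + n_rej != n_in:  # pragma: no cover - conservation guard
        raise AssertionError("row conservation violated in load_consumption")
    if n_rej:
        log.warning("load_consumption: %d of %d rows rejected", n_rej, n_in)
    return records[CONSUMPTION_COLUMNS], rejects.reset_index(drop=True)


def load_profiles(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Load profiles.csv (one row per participant) with plausibility warnings."""
    df = pd.read_csv(path, sep=sep, dtype={"participant_id": str})
    if "participant_id" not in df.columns:
        raise SchemaError("profiles table missing required column 'participant_id'")
    if df["participant_id"].duplicated().any():
        raise SchemaError("duplicate participant_id in profiles")
    for col, (lo, hi) in PROFILE_RANGES.items():
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            n_bad = ((vals < lo) | (vals > hi)).sum()
            if n_bad:
                log.warning("profiles: %d values of %s outside [%s, %s]", n_bad, col, lo, hi)
    return df.set_index("participant_id", drop=False)


@dataclass
class StudyPaths:
    """Paths section of the run config."""

    foods: Path
    consumption: Path
    profiles: Path
    sep: str = ","


def load_study_tables(config: StudyPaths | Mapping | str | Path) -> StudyTables:
    """Load the three study tables named by a :class:`StudyPaths`, a mapping, or a YAML file.

    The YAML layout is ``paths: {foods: ..., consumption: ..., profiles: ...}``
    with an optional top-level ``sep``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
        paths = cfg["paths"] if "paths" in cfg else cfg
        config = StudyPaths(
            foods=Path(paths["foods"]),
            consumption=Path(paths["consumption"]),
            profiles=Path(paths["profiles"]),
            sep=cfg.get("sep", ","),
        )
    elif isinstance(config, Mapping):
        config = StudyPaths(**{k: Path(v) if k != "sep" else v for k, v in config.items()})
    foods = load_food_catalog(config.foods, sep=config.sep)
    consumption, rejects = load_consumption(config.consumption, catalog=foods, sep=config.sep)
    profiles = load_profiles(config.profiles, sep=config.sep)
    return StudyTables(foods=foods, consumption=consumption, profiles=profiles, rejects=rejects)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_group_intakes(
    consumption: pd.DataFrame,
    foods: pd.DataFrame,
    day_filter: Iterable[int] = (1,),
    day_weights: Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Sum food-level grams into GDQS-food-group g/day per (participant, instrument).

    ``grams`` is the sum over member foods on the selected days divided by the
    number of selected days (or a weighted mean of day totals if *day_weights*
    is given, e.g. weekday/weekend 5/7 and 2/7).  Participants with no rows on
    the selected days are omitted with a logged warning.
    """
    days = sorted(set(day_filter))
    if not days:
        raise ValueError("day_filter selects no days")
    sel = consumption[consumption["day_index"].isin(days)].copy()
    dropped = set(consumption["participant_id"]) - set(sel["participant_id"])
    if dropped:
        log.warning("aggregate_group_intakes: %d participants have no rows on days %s",
                    len(dropped), days)
    sel = sel.merge(foods["group_id"], left_on="food_id", right_index=True, how="left")
    if sel["group_id"].isna().any():
        missing = sorted(sel.loc[sel["group_id"].isna(), "food_id"].unique())
        raise KeyError(f"food_ids not in catalog: {missing}")
    if day_weights is None:
        weights = {d: 1.0 / len(days) for d in days}
    else:
        total = sum(day_weights[d] for d in days)
        weights = {d: day_weights[d] / total for d in days}
    sel["wgrams"] = sel["grams"] * sel["day_index"].map(weights)
    out = (
        sel.groupby(["participant_id", "instrument", "group_id"], as_index=False, sort=True)
        ["wgrams"].sum()
        .rename(columns={"wgrams": "grams"})
    )
    return out[GROUP_INTAKE_COLUMNS]


def compute_daily_nutrients(
    consumption: pd.DataFrame,
    foods: pd.DataFrame,
    nutrients: Sequence[str] | None = None,
    missing_policy: str = "propagate",
) -> pd.DataFrame:
    """Per (participant, instrument, day) nutrient totals by linear per-100 g scaling.

    ``intake[n] = sum_foods grams * per100g[n] / 100``.  A food with a missing
    (NaN) composition value makes the day's total for that nutrient NaN under
    the default ``missing_policy="propagate"`` — "not measured" stays
    distinguishable from zero; ``"zero"`` zero-fills instead.  Zero-gram rows
    contribute exactly 0 regardless of composition.
    """
    if missing_policy not in ("propagate", "zero"):
        raise ValueError("missing_policy must be 'propagate' or 'zero'")
    meta_cols = {"name", "group_id"}
    if nutrients is None:
        nutrients = [c for c in foods.columns if c not in meta_cols]
    missing_foods = set(consumption["food_id"]) - set(foods.index)
    if missing_foods:
        raise KeyError(f"food_ids not in catalog: {sorted(missing_foods)}")
    merged = consumption.merge(
        foods[list(nutrients)], left_on="food_id", right_index=True, how="left"
    )
    contrib = merged[list(nutrients)].multiply(merged["grams"] / 100.0, axis=0)
    # 0 g of anything contributes 0 even if its composition is unmeasured
    contrib[merged["grams"] == 0] = 0.0
    if missing_policy == "zero":
        contrib = contrib.fillna(0.0)
    contrib[["participant_id", "instrument", "day_index"]] = merged[
        ["participant_id", "instrument", "day_index"]
    ]
    grouped = contrib.groupby(["participant_id", "instrument", "day_index"], sort=True)
    sums = grouped[list(nutrients)].sum()
    if missing_policy == "propagate":
        has_na = grouped[list(nutrients)].apply(lambda g: g.isna().any())
        sums = sums.mask(has_na)
    return sums.reset_index()


def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> None:
    """Write a report table deterministically (fixed column order, fixed float format)."""
    df.to_csv(path, index=False, float_format=float_format)
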