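"""Deterministic clinical/anthropometric outcome classification and IDF
metabolic-syndrome component counting.

All cut-offs follow WHO / IDF / Asian-population conventions for this study
population and are overridable via :class:`OutcomeThresholds` (or a YAML file)
for other populations.  Every flag is a deterministic function of the profile;
a missing input field yields a missing flag, never an error.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

BMI_CLASSES = ("underweight", "healthy", "overweight", "obese")

MET_S_COMPONENTS = ("abdominal_obesity", "raised_tg", "reduced_hdl",
                    "hypertension", "raised_fpg")


@dataclass(frozen=True)
class OutcomeThresholds:
    bmi_underweight: float = 18.5
    bmi_overweight: float = 25.0     # healthy is [18.5, 25]; 25.0 is healthy
    bmi_obese: float = 30.0
    wc_male: float = 90.0            # abdominal obesity: WC >= threshold
    wc_female: float = 80.0
    whtr: float = 0.5                # waist-to-height ratio > 0.5
    muac_male: float = 30.9          # high MUAC: >= threshold
    muac_female: float = 30.0
    sbp: float = 130.0               # hypertension: SBP >= 130 or DBP >= 85 or meds
    dbp: float = 85.0
    hb_male: float = 130.0           # anemia: Hb < threshold (g/L)
    hb_female: float = 120.0
    tg: float = 150.0                # raised TG: > 150
    hdl_male: float = 40.0           # reduced HDL: < threshold
    hdl_female: float = 50.0
    ldl: float = 160.0               # raised LDL: > 160
    fpg: float = 100.0               # raised FPG: >= 100
    hba1c: float = 6.5               # raised HbA1c: > 6.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OutcomeThresholds":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sex_threshold(sex: pd.Series, male: float, female: float) -> pd.Series:
    out = pd.Series(np.nan, index=sex.index)
    out[sex == "male"] = male
    out[sex == "female"] = female
    return out


def classify_outcomes(
    profiles: pd.DataFrame,
    thresholds: OutcomeThresholds = OutcomeThresholds(),
) -> pd.DataFrame:
    """OutcomeFlags per participant.

    Binary flags are nullable booleans; a flag whose inputs are missing is
    ``<NA>`` while the others are still computed.  Sex-dependent flags are
    missing when sex is missing.
    """
    t = thresholds
    p = profiles
    idx = p.index
    out = pd.DataFrame(index=idx)

    def col(name):
        return pd.to_numeric(p[name], errors="coerce") if name in p.columns \
            else pd.Series(np.nan, index=idx)

    sex = p["sex"] if "sex" in p.columns else pd.Series(pd.NA, index=idx)
    height_m = col("height_cm") / 100.0
    bmi = col("weight_kg") / height_m ** 2
    out["bmi"] = bmi
    out["bmi_class"] = pd.cut(
        bmi,
        bins=[-np.inf, t.bmi_underweight, t.bmi_overweight, t.bmi_obese, np.inf],
        labels=BMI_CLASSES,
        right=True,                   # healthy (18.5, 25] plus the 18.5 edge below
        include_lowest=True,
    )
    # pd.cut's left-open bins put 18.5 in underweight; the printed convention
    # is healthy = [18.5, 25], so fix the single boundary point.
    out.loc[bmi == t.bmi_underweight, "bmi_class"] = "healthy"
    out["overweight_or_obese"] = _ge(bmi, t.bmi_overweight)

    out["high_muac"] = _ge(col("muac_cm"), _sex_threshold(sex, t.muac_male, t.muac_female))
    out["abdominal_obesity"] = _ge(col("wc_cm"), _sex_threshold(sex, t.wc_male, t.wc_female))
    out["whtr_high"] = _gt(col("wc_cm") / col("height_cm"), t.whtr)

    if "on_bp_meds" in p.columns:
        meds = p["on_bp_meds"].astype("boolean").fillna(False)
    else:
        meds = pd.Series(False, index=idx, dtype="boolean")
    # Kleene OR: a missing BP reading stays missing unless medication decides it
    out["hypertension"] = _ge(col("sbp_mmHg"), t.sbp) | _ge(col("dbp_mmHg"), t.dbp) | meds

    out["anemia"] = _lt(col("hb_gL"), _sex_threshold(sex, t.hb_male, t.hb_female))
    out["raised_ldl"] = _gt(col("ldl_mgdL"), t.ldl)
    out["reduced_hdl"] = _lt(col("hdl_mgdL"), _sex_threshold(sex, t.hdl_male, t.hdl_female))
    out["raised_tg"] = _gt(col("tg_mgdL"), t.tg)
    out["raised_fpg"] = _ge(col("fpg_mgdL"), t.fpg)
    out["raised_hba1c"] = _gt(col("hba1c_pct"), t.hba1c)

    comps, mets = count_mets_components(out)
    out["mets_components"] = comps
    out["mets"] = mets
    return out


def _ge(x, thr):
    r = x >= thr
    return r.astype("boolean").mask(pd.isna(x) | pd.isna(thr))


def _gt(x, thr):
    r = x > thr
    return r.astype("boolean").mask(pd.isna(x) | pd.isna(thr))


def _lt(x, thr):
    r = x < thr
    return r.astype("boolean").mask(pd.isna(x) | pd.isna(thr))


def count_mets_components(flags: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """IDF metabolic syndrome: component count (0-5) and the syndrome indicator.

    The five components are abdominal obesity, raised TG, reduced HDL,
    hypertension (BP >= 130/85 or on medication), and raised FPG.  The IDF
    gate requires abdominal obesity plus at least 2 of the other 4.  Any
    missing component makes both outputs missing.
    """
    comp = flags[list(MET_S_COMPONENTS)].astype("boolean")
    any_missing = comp.isna().any(axis=1)
    counts = comp.sum(axis=1).astype("Int64").mask(any_missing)
    others = comp[list(MET_S_COMPONENTS[1:])].sum(axis=1)
    mets = (comp["abdominal_obesity"] & (others >= 2)).mask(any_missing)
    return counts, mets
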