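"""Full-probability nutrient adequacy and the mean probability of adequacy (MPA).

Under the full-probability method a person's probability of meeting their
requirement is ``P = Φ((intake − EAR) / (EAR·CV))``: requirements are normal
with mean EAR and SD EAR·CV, independent of intake.  The MPA is the
arithmetic mean of the adequacy probabilities of six micronutrients
(vitamin A, thiamine, vitamin B12, calcium, iron, zinc); protein adequacy is
reported separately.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MPA_NUTRIENTS = ("vitamin_a", "thiamine", "vitamin_b12", "calcium", "iron", "zinc")


@dataclass(frozen=True)
class RequirementSpec:
    """Requirement distribution for one nutrient: N(EAR, (EAR·CV)²)."""

    nutrient: str
    ear: float
    cv: float
    per_kg: bool = False
    units: str = ""
    source: str = ""

    def __post_init__(self):
        if self.ear <= 0:
            raise ValueError(f"{self.nutrient}: EAR must be > 0")
        if not (0 < self.cv < 1):
            raise ValueError(f"{self.nutrient}: CV must be in (0, 1)")


def load_requirements(path: str | Path | None = None) -> dict[str, RequirementSpec]:
    """Load requirements.csv: nutrient,ear,units,per_kg,cv,source."""
    if path is None:
        path = Path(resources.files("dietmetrics").joinpath("data", "requirements.csv"))
    df = pd.read_csv(path)
    return {
        row["nutrient"]: RequirementSpec(
            nutrient=row["nutrient"], ear=float(row["ear"]), cv=float(row["cv"]),
            per_kg=bool(int(row.get("per_kg", 0))), units=str(row.get("units", "")),
            source=str(row.get("source", "")),
        )
        for _, row in df.iterrows()
    }


def probability_of_adequacy(
    usual_intake: float | np.ndarray,
    spec: RequirementSpec,
    body_weight_kg: float | np.ndarray | None = None,
) -> np.ndarray:
    """P(usual intake exceeds the person's requirement) under the normal model.

    Per-kg specs (e.g. protein in g/kg/d) scale the EAR by body weight first;
    omitting the weight for such a spec is an error.  Strictly increasing in
    intake; intake = EAR gives exactly 0.5.
    """
    intake = np.asarray(usual_intake, dtype=float)
    if np.any(intake[np.isfinite(intake)] < 0):
        raise ValueError("usual intake must be >= 0")
    ear = spec.ear
    if spec.per_kg:
        if body_weight_kg is None:
            raise ValueError(f"{spec.nutrient}: per-kg requirement needs body weight")
        ear = spec.ear * np.asarray(body_weight_kg, dtype=float)
    return stats.norm.cdf((intake - ear) / (ear * spec.cv))


def mean_probability_adequacy(
    probs: Mapping[str, float] | pd.DataFrame,
    micronutrients: Sequence[str] = MPA_NUTRIENTS,
    policy: str = "strict",
) -> float | pd.Series:
    """Arithmetic mean of the six micronutrient adequacy probabilities.

    Default policy ``"strict"``: any missing micronutrient probability makes
    the MPA missing (no renormalisation).  ``"pairwise"`` averages whatever is
    present.
    """
    if policy not in ("strict", "pairwise"):
        raise ValueError("policy must be 'strict' or 'pairwise'")
    if isinstance(probs, pd.DataFrame):
        missing_cols = [m for m in micronutrients if m not in probs.columns]
        if missing_cols:
            raise KeyError(f"missing micronutrient columns: {missing_cols}")
        sub = probs[list(micronutrients)]
        return sub.mean(axis=1, skipna=(policy == "pairwise"))
    vals = [probs.get(m) for m in micronutrients]
    present = [v for v in vals if v is not None and np.isfinite(v)]
    if policy == "strict" and len(present) != len(micronutrients):
        return float("nan")
    return float(np.mean(present)) if present else float("nan")


def adequacy_table(
    usual_intakes: pd.DataFrame,
    requirements: Mapping[str, RequirementSpec],
    body_weights: pd.Series | None = None,
    intake_col: str = "usual",
) -> pd.DataFrame:
    """Per-participant adequacy probabilities, MPA, and protein probability.

    *usual_intakes* is long form (participant_id, nutrient, <intake_col>);
    *body_weights* maps participant_id -> kg for per-kg requirements.
    Returns one row per participant with a column per nutrient plus ``mpa``.
    """
    wide = usual_intakes.pivot(index="participant_id", columns="nutrient",
                               values=intake_col)
    out = pd.DataFrame(index=wide.index)
    for nut, spec in requirements.items():
        if nut not in wide.columns:
            continue
        bw = None
        if spec.per_kg:
            if body_weights is None:
                raise ValueError(f"{nut}: per-kg requirement needs body weights")
            bw = wide.index.map(body_weights).to_numpy(dtype=float)
        intake = wide[nut].to_numpy(dtype=float)
        p = np.full(len(intake), np.nan)
        ok = np.isfinite(intake)
        if bw is not None:
            ok &= np.isfinite(bw)
            p[ok] = probability_of_adequacy(intake[ok], spec, bw[ok])
        else:
            p[ok] = probability_of_adequacy(intake[ok], spec)
        out[nut] = p
    out["mpa"] = mean_probability_adequacy(out, policy="strict")
    return out.reset_index()


def prevalence_summary(adequacy: pd.DataFrame, nutrients: Sequence[str]) -> pd.DataFrame:
    """Population summaries per nutrient, both readings of "% adequacy":

    ``mean_probability_pct`` — mean of individual probabilities × 100;
    ``share_above_half_pct`` — share of participants with probability > 0.5.
    """
    rows = []
    for nut in nutrients:
        p = adequacy[nut].dropna()
        rows.append({
            "nutrient": nut,
            "mean_probability_pct": 100.0 * p.mean() if len(p) else np.nan,
            "share_above_half_pct": 100.0 * (p > 0.5).mean() if len(p) else np.nan,
            "n": len(p),
        })
    return pd.DataFrame(rows)
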