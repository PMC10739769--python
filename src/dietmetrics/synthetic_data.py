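"""Synthetic dietary-validation study generator.

Emulates the design of an app-validation survey: ~600 adults aged 40-60
(about three-quarters female), two replicate recall days (one weekday, one
weekend day) each captured by an app-style instrument (group-level portions
snapped to a reference-cube set) and a conventional 24-h recall (food-level
grams with multiplicative reporting error), plus a habitual-intake FFQ.

The statistical device is a single latent diet-quality factor L ~ N(0, 1):

* each food group's usual log-intake loads on L (healthy groups positively,
  unhealthy negatively) with between-person (σ_b) and within-person (σ_w)
  log-scale variance components and a per-day consumption probability
  (unhealthy groups are not consumed daily by everyone);
* clinical outcomes are linear (continuous) or logistic (binary) functions
  of L with configurable coefficients, inducing the sign pattern a real
  diet-quality factor shows (positive with micronutrient adequacy, HDL,
  urinary potassium; negative with adiposity, diastolic BP, sodium screener);
* covariates are mildly correlated with L (confounding, switchable off).

Every default magnitude is illustrative, not an estimate of any real study;
all of them sit in :class:`SimConfig`.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .metric_scoring import CubeSet, GDQSScoreTable, ScreenerConfig, quantize_with_cubes

NUTRIENTS = ("energy_kcal", "protein", "vitamin_a", "thiamine", "vitamin_b12",
             "calcium", "iron", "zinc")

#: Per-100 g composition by food group (energy kcal, protein g, vitamin A RAE,
#: thiamine mg, B12 ug, calcium mg, iron mg, zinc mg). Entirely synthetic,
#: shaped so that micronutrients come predominantly from the healthy groups.
GROUP_COMPOSITION: dict[str, tuple[float, ...]] = {
    "citrus_fruits":               (45, 0.7, 10, 0.04, 0.0, 26, 0.3, 0.1),
    "deep_orange_fruits":          (60, 0.6, 80, 0.04, 0.0, 12, 0.3, 0.1),
    "other_fruits":                (60, 0.5, 5, 0.03, 0.0, 10, 0.3, 0.1),
    "dark_green_leafy_vegetables": (30, 2.5, 300, 0.08, 0.0, 120, 4.0, 0.4),
    "cruciferous_vegetables":      (25, 1.8, 30, 0.05, 0.0, 40, 0.7, 0.3),
    "deep_orange_vegetables":      (35, 0.9, 830, 0.05, 0.0, 30, 0.4, 0.2),
    "other_vegetables":            (28, 1.2, 20, 0.04, 0.0, 25, 0.5, 0.3),
    "legumes":                     (120, 8.0, 2, 0.20, 0.0, 50, 3.5, 1.2),
    "deep_orange_tubers":          (90, 1.5, 700, 0.08, 0.0, 25, 0.6, 0.3),
    "nuts_seeds":                  (600, 20.0, 1, 0.50, 0.0, 70, 2.5, 3.0),
    "whole_grains":                (110, 3.5, 0, 0.15, 0.0, 12, 1.2, 1.3),
    "liquid_oils":                 (884, 0.0, 0, 0.0, 0.0, 0, 0.0, 0.0),
    "fish_shellfish":              (120, 20.0, 15, 0.08, 0.9, 60, 1.5, 0.8),
    "poultry_game_meat":           (170, 20.0, 15, 0.08, 0.35, 12, 1.0, 1.5),
    "low_fat_dairy":               (50, 3.4, 30, 0.04, 0.45, 120, 0.1, 0.4),
    "eggs":                        (140, 12.5, 160, 0.07, 1.1, 50, 1.8, 1.1),
    "white_roots_tubers":          (80, 1.5, 1, 0.08, 0.0, 12, 0.5, 0.3),
    "processed_meat":              (280, 13.0, 5, 0.25, 0.8, 10, 0.9, 1.6),
    "refined_grains_baked_goods":  (130, 2.4, 0, 0.12, 0.0, 4, 0.5, 0.6),
    "sweets_ice_cream":            (350, 4.0, 40, 0.03, 0.1, 80, 0.4, 0.3),
    "sugar_sweetened_beverages":   (40, 0.0, 0, 0.0, 0.0, 2, 0.0, 0.0),
    "juice":                       (45, 0.3, 10, 0.03, 0.0, 8, 0.2, 0.0),
    "purchased_deep_fried_foods":  (300, 8.0, 10, 0.10, 0.2, 25, 0.8, 0.7),
    "red_meat":                    (220, 19.0, 3, 0.75, 1.6, 8, 2.2, 4.5),
    "high_fat_dairy":              (90, 3.2, 45, 0.03, 0.4, 115, 0.1, 0.4),
}

HEALTHY_GROUPS = (
    "citrus_fruits", "deep_orange_fruits", "other_fruits",
    "dark_green_leafy_vegetables", "cruciferous_vegetables",
    "deep_orange_vegetables", "other_vegetables", "legumes",
    "deep_orange_tubers", "nuts_seeds", "whole_grains", "liquid_oils",
    "fish_shellfish", "poultry_game_meat", "low_fat_dairy", "eggs",
)

#: (median g/day, per-day consumption probability) by group.
GROUP_DIET = {
    "citrus_fruits": (30, 0.55), "deep_orange_fruits": (40, 0.6),
    "other_fruits": (80, 0.65), "dark_green_leafy_vegetables": (40, 0.7),
    "cruciferous_vegetables": (40, 0.6), "deep_orange_vegetables": (25, 0.7),
    "other_vegetables": (80, 0.95), "legumes": (30, 0.6),
    "deep_orange_tubers": (15, 0.3), "nuts_seeds": (10, 0.5),
    "whole_grains": (30, 0.5), "liquid_oils": (18, 0.9),
    "fish_shellfish": (80, 0.85), "poultry_game_meat": (50, 0.8),
    "low_fat_dairy": (60, 0.7), "eggs": (40, 0.8),
    "white_roots_tubers": (40, 0.6), "processed_meat": (15, 0.4),
    "refined_grains_baked_goods": (300, 1.0), "sweets_ice_cream": (30, 0.55),
    "sugar_sweetened_beverages": (150, 0.6), "juice": (30, 0.3),
    "purchased_deep_fried_foods": (30, 0.5), "red_meat": (40, 0.6),
    "high_fat_dairy": (30, 0.5),
}


@dataclass(frozen=True)
class GroupSim:
    """Simulation parameters for one food group's usual intake (log scale)."""

    mu_log: float          # median daily grams on consumption days, log scale
    sigma_b: float         # between-person SD of usual log intake
    sigma_w: float         # within-person day-to-day SD
    loading: float         # coefficient of latent diet quality L
    p_consume: float       # per-day probability the group is consumed at all


def _default_groups() -> dict[str, GroupSim]:
    out = {}
    for gid, (median_g, p) in GROUP_DIET.items():
        healthy = gid in HEALTHY_GROUPS
        staple = gid in ("refined_grains_baked_goods", "white_roots_tubers",
                         "liquid_oils")
        loading = 0.15 if staple else (0.35 if healthy else -0.35)
        if staple and not healthy:
            loading = -0.15
        out[gid] = GroupSim(mu_log=float(np.log(median_g)), sigma_b=0.45,
                            sigma_w=0.55, loading=loading, p_consume=p)
    return out


#: Continuous outcomes: mean, coefficient on L, residual SD (sex-specific
#: bases where relevant). Signs mimic a protective diet-quality factor.
DEFAULT_OUTCOME_LOADINGS = {
    "bmi": -0.9, "fat_pct": -1.5, "wc_extra": -0.6,
    "sbp": -1.5, "dbp": -1.7, "hdl": 1.9, "tg_log": -0.12,
    "fpg_log": -0.04, "hba1c": -0.08, "hb": 0.8,
    "urine_k": 115.0, "urine_na": -60.0, "screener": -0.55,
}


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters; defaults encode the emulated survey conditions."""

    seed: int                                   # mandatory
    n_participants: int = 600
    prop_female: float = 0.756
    age_range: tuple[float, float] = (40.0, 60.0)
    n_recall_days: int = 2
    group_params: Mapping[str, GroupSim] = field(default_factory=_default_groups)
    outcome_loadings: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_LOADINGS))
    sigma_24hr: float = 0.15        # lognormal reporting error SD, 24HR foods
    sigma_ffq: float = 0.35         # lognormal error SD, FFQ
    ffq_scale: float = 1.2          # systematic FFQ over-report factor
    cube_set: CubeSet = field(default_factory=CubeSet.from_yaml)
    confounding: bool = True        # mild covariate-L correlation
    prop_staff: float = 0.248
    quantize_app: bool = True

    def __post_init__(self):
        if not (0 <= self.prop_female <= 1):
            raise ValueError("prop_female must be in [0, 1]")
        if self.n_recall_days < 1 or self.n_participants < 1:
            raise ValueError("invalid design sizes")
        for gid, g in self.group_params.items():
            if g.sigma_b < 0 or g.sigma_w < 0 or not (0 <= g.p_consume <= 1):
                raise ValueError(f"invalid group parameters for {gid}")

    def null(self) -> "SimConfig":
        """Copy with every diet and outcome loading set to 0 (global null)."""
        groups = {gid: dataclasses.replace(g, loading=0.0)
                  for gid, g in self.group_params.items()}
        return dataclasses.replace(
            self, group_params=groups,
            outcome_loadings={k: 0.0 for k in self.outcome_loadings},
            confounding=False)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, Mapping):
                return {k: enc(v) for k, v in sorted(o.items())}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o
        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SyntheticStudy:
    """A complete simulated study plus the generating truth."""

    foods: pd.DataFrame
    consumption: pd.DataFrame
    profiles: pd.DataFrame
    truth_latent: pd.DataFrame          # participant_id, L
    truth_group_usual: pd.DataFrame     # participant_id, group_id, grams
    truth_nutrient_usual: pd.DataFrame  # participant_id, nutrient, amount
    manifest: dict


def build_food_catalog() -> pd.DataFrame:
    """Two member foods per group with the group's composition varied ±15%.

    Food shares within a group are fixed (65/35), so decomposition and
    re-aggregation round-trip exactly.
    """
    rows = []
    for gid, comp in GROUP_COMPOSITION.items():
        for j, factor in enumerate((1.15, 0.85)):
            rows.append({
                "food_id": f"{gid}__f{j}", "name": f"{gid} food {j}",
                "group_id": gid,
                **{n: round(c * factor, 4) for n, c in zip(NUTRIENTS, comp)},
            })
    return pd.DataFrame(rows).set_index("food_id")


FOOD_SHARES = (0.65, 0.35)


def _participant_ids(n: int) -> np.ndarray:
    return np.array([f"P{i:04d}" for i in range(1, n + 1)])


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Participant profiles and the latent diet-quality factor L ~ N(0, 1)."""
    rng = np.random.default_rng([config.seed, 100])
    n = config.n_participants
    pid = _participant_ids(n)
    L = rng.standard_normal(n)
    load = dict(config.outcome_loadings)
    female = rng.random(n) < config.prop_female
    sex = np.where(female, "female", "male")
    age = rng.uniform(*config.age_range, n)
    conf = 0.10 if config.confounding else 0.0
    edu_latent = rng.standard_normal(n) + conf * L
    education = np.digitize(edu_latent, [-0.9, 0.4]) + 1      # 1..3 ordinal
    met = np.exp(rng.normal(6.2 + conf * L, 1.1))
    smoker = rng.random(n) < np.where(female, 0.015, 0.205)
    psqi = np.clip(rng.normal(6.0, 2.5, n), 0, 21).round(0)
    staff = rng.random(n) < config.prop_staff

    height = np.where(female, rng.normal(156, 5.6, n), rng.normal(168.8, 5.6, n))
    bmi = 25.5 + load["bmi"] * L + rng.normal(0, 4.3, n)
    bmi = np.clip(bmi, 15, 55)
    weight = bmi * (height / 100.0) ** 2
    wc_base = np.where(female, 80.5, 87.0)
    wc = wc_base + 2.1 * (bmi - 25.5) + load["wc_extra"] * L + rng.normal(0, 4.0, n)
    muac = 30.4 + 0.55 * (bmi - 25.5) + rng.normal(0, 1.8, n)
    fat_base = np.where(female, 35.6, 25.5)
    fat = np.clip(fat_base + load["fat_pct"] * L + rng.normal(0, 6.2, n), 5, 60)
    sbp = 121 + load["sbp"] * L + rng.normal(0, 17, n)
    dbp = 80 + load["dbp"] * L + rng.normal(0, 11, n)
    on_meds = rng.random(n) < 0.14
    hb = np.where(female, 125.4, 144.9) + load["hb"] * L + rng.normal(0, 12, n)
    total_chol = rng.normal(213, 43, n)
    ldl = rng.normal(147, 40, n)
    hdl = np.where(female, 55, 47) + load["hdl"] * L + rng.normal(0, 11, n)
    tg = np.exp(np.log(110) + load["tg_log"] * L + rng.normal(0, 0.45, n))
    fpg = np.exp(np.log(100) + load["fpg_log"] * L + rng.normal(0, 0.22, n))
    hba1c = np.clip(5.8 + load["hba1c"] * L + rng.normal(0, 1.0, n), 4, 15)
    urine_na = np.clip(3400 + load["urine_na"] * L + rng.normal(0, 1400, n), 200, None)
    urine_k = np.clip(1525 + load["urine_k"] * L + rng.normal(0, 530, n), 100, None)

    profiles = pd.DataFrame({
        "participant_id": pid, "age_y": age.round(1), "sex": sex,
        "education": education, "met_min_wk": met.round(0),
        "smoker": smoker, "psqi_score": psqi,
        "study_group": np.where(staff, "staff", "community"),
        "weight_kg": weight.round(1), "height_cm": height.round(1),
        "muac_cm": muac.round(1), "wc_cm": wc.round(1),
        "fat_pct": fat.round(1), "sbp_mmHg": sbp.round(0),
        "dbp_mmHg": dbp.round(0), "on_bp_meds": on_meds,
        "hb_gL": hb.round(1), "total_chol_mgdL": total_chol.round(0),
        "ldl_mgdL": ldl.round(0), "hdl_mgdL": hdl.round(0),
        "tg_mgdL": tg.round(0), "fpg_mgdL": fpg.round(0),
        "hba1c_pct": hba1c.round(2),
        "urine_na_mg": urine_na.round(0), "urine_k_mg": urine_k.round(0),
    })

    # sodium screener item responses from a latent salt propensity
    scr = ScreenerConfig.from_yaml()
    s = load["screener"] * L + rng.standard_normal(n)
    for item, (max_level, _w) in scr.items.items():
        mu = 0.8 if item.startswith("freq_") else 0.7
        x = np.clip(np.round(mu + 0.55 * s + rng.normal(0, 0.9, n)), 0, max_level)
        profiles[item] = x.astype(int)

    profiles = profiles.set_index("participant_id", drop=False)
    return profiles, pd.Series(L, index=pid, name="L")


def _usual_group_log_intakes(L: pd.Series, config: SimConfig) -> pd.DataFrame:
    """Per-person usual log median intake per group (shared by all instruments)."""
    rng = np.random.default_rng([config.seed, 101])
    n = len(L)
    data = {}
    for gid in sorted(config.group_params):
        g = config.group_params[gid]
        data[gid] = g.mu_log + g.loading * L.to_numpy() + rng.normal(0, g.sigma_b, n)
    return pd.DataFrame(data, index=L.index)


def _decompose_to_foods(group_grams: pd.DataFrame, value_name: str) -> pd.DataFrame:
    """Split group-level grams into the two member foods at fixed shares."""
    long = group_grams.reset_index(names="participant_id").melt(
        id_vars="participant_id", var_name="group_id", value_name=value_name)
    long = long[long[value_name] > 0]
    parts = []
    for j, share in enumerate(FOOD_SHARES):
        p = long.copy()
        p["food_id"] = p["group_id"] + f"__f{j}"
        p[value_name] = p[value_name] * share
        parts.append(p)
    return pd.concat(parts, ignore_index=True)


def generate_diet_days(
    profiles: pd.DataFrame, L: pd.Series, config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-day consumption for the app and 24HR instruments.

    Both instruments observe the same underlying eating days: the 24HR
    reports food-level grams with multiplicative lognormal error; the app
    reports the day's group totals snapped to the cube set.  Returns
    ``(consumption, truth_group_usual)``.
    """
    rng = np.random.default_rng([config.seed, 102])
    usual_log = _usual_group_log_intakes(L, config)
    n = len(L)
    gids = list(usual_log.columns)
    frames = []
    for day in range(1, config.n_recall_days + 1):
        eaten = pd.DataFrame(index=usual_log.index, columns=gids, dtype=float)
        for gid in gids:
            g = config.group_params[gid]
            consumed = rng.random(n) < g.p_consume
            grams = np.exp(usual_log[gid].to_numpy() + rng.normal(0, g.sigma_w, n))
            eaten[gid] = np.where(consumed, grams, 0.0)
        # 24HR: food-level with reporting error
        foods24 = _decompose_to_foods(eaten, "grams")
        if config.sigma_24hr > 0:
            err = rng.normal(0, config.sigma_24hr, len(foods24))
            foods24["grams"] = foods24["grams"] * np.exp(err)
        foods24["instrument"] = "recall24"
        foods24["day_index"] = day
        # app: group totals through the cube quantizer, booked on food 0
        app = eaten.copy()
        if config.quantize_app:
            for gid in gids:
                app[gid] = [quantize_with_cubes(v, gid, config.cube_set)
                            for v in app[gid]]
        app_long = app.reset_index(names="participant_id").melt(
            id_vars="participant_id", var_name="group_id", value_name="grams")
        app_long = app_long[app_long["grams"] > 0].copy()
        app_long["food_id"] = app_long["group_id"] + "__f0"
        app_long["instrument"] = "app"
        app_long["day_index"] = day
        frames.append(foods24[["participant_id", "instrument", "day_index",
                               "food_id", "grams"]])
        frames.append(app_long[["participant_id", "instrument", "day_index",
                                "food_id", "grams"]])
    consumption = pd.concat(frames, ignore_index=True)

    truth_rows = []
    for gid in gids:
        g = config.group_params[gid]
        expected = g.p_consume * np.exp(usual_log[gid] + g.sigma_w ** 2 / 2.0)
        truth_rows.append(pd.DataFrame({
            "participant_id": usual_log.index, "group_id": gid,
            "grams": expected.to_numpy(),
        }))
    truth = pd.concat(truth_rows, ignore_index=True)
    return consumption, truth


def generate_ffq_intakes(
    profiles: pd.DataFrame, L: pd.Series, config: SimConfig,
) -> pd.DataFrame:
    """FFQ consumption (day_index 0, g/day habitual equivalents).

    FFQ grams are the true usual intake times a lognormal error with its own
    SD and a systematic scale factor (> 1 reproduces FFQ-derived metric
    scores exceeding recall-derived ones).
    """
    rng = np.random.default_rng([config.seed, 103])
    usual_log = _usual_group_log_intakes(L, config)
    gids = list(usual_log.columns)
    usual = pd.DataFrame(index=usual_log.index, columns=gids, dtype=float)
    for gid in gids:
        g = config.group_params[gid]
        usual[gid] = g.p_consume * np.exp(usual_log[gid] + g.sigma_w ** 2 / 2.0)
    err = pd.DataFrame(
        np.exp(rng.normal(0, config.sigma_ffq, usual.shape)) if config.sigma_ffq > 0
        else np.ones(usual.shape),
        index=usual.index, columns=gids)
    reported = usual * err * config.ffq_scale
    ffq = _decompose_to_foods(reported, "grams")
    ffq["instrument"] = "ffq"
    ffq["day_index"] = 0
    return ffq[["participant_id", "instrument", "day_index", "food_id", "grams"]]


def generate_study(config: SimConfig) -> SyntheticStudy:
    """Compose cohort, diet days, and FFQ into a complete synthetic study."""
    foods = build_food_catalog()
    profiles, L = generate_cohort(config)
    consumption_days, truth_group = generate_diet_days(profiles, L, config)
    ffq = generate_ffq_intakes(profiles, L, config)
    consumption = pd.concat([consumption_days, ffq], ignore_index=True)
    consumption["grams"] = consumption["grams"].round(4)

    nutrient_rows = []
    comp = foods.drop(columns=["name", "group_id"])
    group_comp = {}
    for gid in truth_group["group_id"].unique():
        per100 = sum(comp.loc[f"{gid}__f{j}"] * share
                     for j, share in enumerate(FOOD_SHARES))
        group_comp[gid] = per100
    tg = truth_group.copy()
    for nut in NUTRIENTS:
        tg[nut] = tg["grams"] * tg["group_id"].map(
            {g: c[nut] for g, c in group_comp.items()}) / 100.0
    truth_nutrient = (
        tg.groupby("participant_id")[list(NUTRIENTS)].sum()
        .reset_index()
        .melt(id_vars="participant_id", var_name="nutrient", value_name="amount")
    )
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "n_participants": config.n_participants}
    return SyntheticStudy(
        foods=foods, consumption=consumption, profiles=profiles,
        truth_latent=pd.DataFrame({"participant_id": L.index, "L": L.to_numpy()}),
        truth_group_usual=truth_group, truth_nutrient_usual=truth_nutrient,
        manifest=manifest,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the study tables in the loader's file formats plus truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "foods.csv": study.foods.reset_index(),
        "consumption.csv": study.consumption,
        "profiles.csv": study.profiles.reset_index(drop=True),
        "truth_latent.csv": study.truth_latent,
        "truth_group_usual.csv": study.truth_group_usual,
        "truth_nutrient_usual.csv": study.truth_nutrient_usual,
    }
    for name, df in tables.items():
        p = outdir / name
        df.to_csv(p, index=False, float_format="%.10g")
        paths[name] = p
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(study.manifest, fh, indent=2, sort_keys=True)
    paths["manifest.json"] = outdir / "manifest.json"
    return paths
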