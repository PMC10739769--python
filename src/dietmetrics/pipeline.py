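"""End-to-end orchestration: simulate (or load) -> score metrics -> usual
intakes -> adequacy -> outcomes -> comparison statistics -> report tables.

Every stochastic stage is keyed off the run seed, so a run with the same
config and seed is byte-reproducible.  Report tables are written at full
precision plus a display-rounded copy, with a column dictionary.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__
from .adequacy import MPA_NUTRIENTS, adequacy_table, load_requirements, prevalence_summary
from .comparison_stats import (
    assign_quintiles, concordance_correlation, fit_quintile_model,
    per_sd_association, spearman_matrix, wald_trend_difference,
    wolfe_dependent_correlation_test,
)
from .metric_scoring import (
    AHEIConfig, GDQSScoreTable, GDRConfig, MDDWConfig, ScreenerConfig,
    score_ahei, score_gdqs, score_gdr, score_mddw, score_sodium_screener,
)
from .outcomes import classify_outcomes
from .study_io import StudyTables, aggregate_group_intakes, compute_daily_nutrients, load_study_tables
from .synthetic_data import NUTRIENTS, SimConfig, SyntheticStudy, generate_study

log = logging.getLogger("dietmetrics")

METRICS = ("gdqs_app", "gdqs_24", "gdqs_ffq", "mddw_24", "mddw_ffq",
           "ahei_24", "ahei_ffq", "gdr_24")

CONTINUOUS_OUTCOMES = ("mpa_24_pct", "mpa_ffq_pct", "protein_prob_24_pct",
                       "bmi", "fat_pct", "sbp_mmHg", "dbp_mmHg", "hdl_mgdL",
                       "urine_na_mg", "urine_k_mg", "sodium_screener")
BINARY_OUTCOMES = ("overweight_or_obese", "high_muac", "abdominal_obesity",
                   "hypertension", "anemia", "reduced_hdl", "raised_tg",
                   "raised_fpg", "mets")


@dataclass
class RunConfig:
    """Single config object driving a whole validation run."""

    seed: int
    sim: SimConfig | None = None         # simulate when set ...
    paths: dict | None = None            # ... else load these study files
    covariates: tuple[str, ...] = ("age_y", "female", "education", "met_min_wk",
                                   "smoker", "psqi_score", "staff")
    metrics: tuple[str, ...] = METRICS
    continuous_outcomes: tuple[str, ...] = CONTINUOUS_OUTCOMES
    binary_outcomes: tuple[str, ...] = BINARY_OUTCOMES
    pairwise: bool = True
    pairwise_outcomes: tuple[str, ...] = ("mpa_24_pct", "bmi", "hdl_mgdL",
                                          "abdominal_obesity")
    n_boot: int = 200
    include_timestamps: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        if seed is not None:
            cfg["seed"] = seed
        if "seed" not in cfg:
            raise ValueError("run config must specify a seed")
        if "sim" in cfg and cfg["sim"] is not None:
            sim = dict(cfg["sim"])
            sim.setdefault("seed", cfg["seed"])
            cfg["sim"] = SimConfig(**sim)
        elif "paths" not in cfg:
            cfg["sim"] = SimConfig(seed=cfg["seed"])
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: tuple(v) if isinstance(v, list) else v
                      for k, v in cfg.items() if k in known})


# ---------------------------------------------------------------------------
# Stage: metric scoring
# ---------------------------------------------------------------------------

def compute_metric_table(
    foods: pd.DataFrame, consumption: pd.DataFrame, profiles: pd.DataFrame,
) -> pd.DataFrame:
    """All metric scores per participant, one column per metric-instrument pair.

    Metrics are scored from day 1 only for the app and 24HR pathways (survey
    convention: one recall day per person) and from the habitual (day 0)
    intakes for the FFQ; the sodium screener comes from the profile items.
    """
    gdqs_table = GDQSScoreTable.from_csv()
    mddw_cfg = MDDWConfig.from_yaml()
    ahei_cfg = AHEIConfig.from_yaml()
    gdr_cfg = GDRConfig.from_yaml()
    scr_cfg = ScreenerConfig.from_yaml()

    screener = score_sodium_screener(profiles, scr_cfg)
    day = consumption[consumption["instrument"].isin(["app", "recall24"])]
    gi1 = aggregate_group_intakes(day, foods, day_filter=(1,))
    ffq = consumption[consumption["instrument"] == "ffq"]
    gif = aggregate_group_intakes(ffq, foods, day_filter=(0,)) if len(ffq) else None
    gi = pd.concat([gi1, gif], ignore_index=True) if gif is not None else gi1

    suffix = {"app": "app", "recall24": "24", "ffq": "ffq"}

    def widen(df, value_col, prefix):
        w = df.pivot(index="participant_id", columns="instrument", values=value_col)
        return w.rename(columns={c: f"{prefix}_{suffix[c]}" for c in w.columns})

    out = widen(score_gdqs(gi, gdqs_table), "gdqs_total", "gdqs")
    gdqs_parts = score_gdqs(gi, gdqs_table)
    for part in ("gdqs_plus", "gdqs_minus"):
        out = out.join(widen(gdqs_parts, part, part))
    non_app = gi[gi["instrument"] != "app"]
    out = out.join(widen(score_mddw(non_app, mddw_cfg), "mddw_count", "mddw"))
    out = out.join(widen(score_ahei(non_app, ahei_cfg, sodium_screener=screener),
                         "ahei_total", "ahei"))
    gdr24 = gi1[gi1["instrument"] == "recall24"]
    out = out.join(widen(score_gdr(gdr24, gdr_cfg), "gdr_total", "gdr"))
    out["sodium_screener"] = out.index.map(screener)
    out.index.name = "participant_id"
    return out


# ---------------------------------------------------------------------------
# Stage: nutrients and adequacy
# ---------------------------------------------------------------------------

def compute_adequacy_outcomes(
    foods: pd.DataFrame, consumption: pd.DataFrame, profiles: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Energy-adjusted adequacy outcomes per participant for 24HR and FFQ.

    24HR daily nutrients go through Box-Cox shrinkage to usual intakes; FFQ
    intakes (already habitual) use person means.  Both are residual
    energy-adjusted before the full-probability adequacy step.
    """
    from .usual_intake import usual_intake_table

    requirements = load_requirements()
    weights = profiles.set_index("participant_id")["weight_kg"] \
        if "weight_kg" in profiles.columns else None
    nutrients = [n for n in NUTRIENTS]
    out = {}
    tables = {}
    for instrument, label, shrink, days in (
        ("recall24", "24", True, None), ("ffq", "ffq", False, None),
    ):
        sub = consumption[consumption["instrument"] == instrument]
        if not len(sub):
            continue
        daily = compute_daily_nutrients(sub, foods, nutrients=nutrients)
        usual = usual_intake_table(daily, nutrients, shrink=shrink)
        adeq = adequacy_table(usual, requirements, body_weights=weights,
                              intake_col="usual_energy_adjusted")
        adeq = adeq.set_index("participant_id")
        out[f"mpa_{label}_pct"] = 100.0 * adeq["mpa"]
        if "protein" in adeq.columns:
            out[f"protein_prob_{label}_pct"] = 100.0 * adeq["protein"]
        tables[label] = adeq
    return pd.DataFrame(out), tables


def _covariate_design(profiles: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric covariate matrix: sex -> female dummy, study_group -> staff dummy."""
    p = profiles.set_index("participant_id") if "participant_id" in profiles.columns \
        else profiles
    X = pd.DataFrame(index=p.index)
    for c in covariates:
        if c == "female":
            X[c] = (p["sex"] == "female").astype(float)
        elif c == "staff":
            X[c] = (p["study_group"] == "staff").astype(float)
        elif c == "smoker":
            X[c] = p["smoker"].astype(float)
        else:
            X[c] = pd.to_numeric(p[c], errors="coerce")
    return X


# ---------------------------------------------------------------------------
# Stage: statistics
# ---------------------------------------------------------------------------

def _metric_instrument_family(name: str) -> str:
    return name.rsplit("_", 1)[0]


def run_validation_study(
    config: RunConfig,
    outdir: str | Path | None = None,
    study: SyntheticStudy | StudyTables | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full validation analysis; returns the report tables.

    *study* may be supplied directly; otherwise it is simulated from
    ``config.sim`` or loaded from ``config.paths``.  Writes the report to
    *outdir* when given.
    """
    t0 = time.time()
    if study is None:
        if config.sim is not None:
            study = generate_study(config.sim)
        elif config.paths is not None:
            study = load_study_tables(config.paths)
        else:
            raise ValueError("config must provide sim or paths")
    foods, consumption, profiles = study.foods, study.consumption, study.profiles
    log.info("stage inputs ready (%.1fs)", time.time() - t0)

    metrics = compute_metric_table(foods, consumption, profiles)
    adeq_out, adeq_tables = compute_adequacy_outcomes(foods, consumption, profiles)
    flags = classify_outcomes(profiles.set_index("participant_id")
                              if "participant_id" in profiles.columns else profiles)
    log.info("stages score/adequacy/outcomes done (%.1fs)", time.time() - t0)

    pidx = metrics.index
    prof = profiles.set_index("participant_id") if "participant_id" in profiles.columns \
        else profiles
    outcome_df = pd.DataFrame(index=pidx)
    for col in config.continuous_outcomes:
        if col in adeq_out.columns:
            outcome_df[col] = adeq_out[col].reindex(pidx)
        elif col in metrics.columns:
            outcome_df[col] = metrics[col]
        elif col in flags.columns:
            outcome_df[col] = pd.to_numeric(flags[col].reindex(pidx), errors="coerce")
        elif col in prof.columns:
            outcome_df[col] = pd.to_numeric(prof[col].reindex(pidx), errors="coerce")
    for col in config.binary_outcomes:
        if col in flags.columns:
            outcome_df[col] = flags[col].reindex(pidx).astype("boolean").astype("Float64")

    mcols = [m for m in config.metrics if m in metrics.columns]
    X = _covariate_design(prof, config.covariates).reindex(pidx)

    tables: dict[str, pd.DataFrame] = {}

    # --- metric summaries with across-instrument ANOVA
    rows = []
    families: dict[str, list[str]] = {}
    for m in mcols:
        families.setdefault(_metric_instrument_family(m), []).append(m)
    sex = prof["sex"].reindex(pidx) if "sex" in prof.columns else pd.Series(index=pidx)
    for fam, members in families.items():
        groups = [metrics[m].dropna() for m in members]
        p_anova = sps.f_oneway(*groups).pvalue if len(members) > 1 else np.nan
        for m in members:
            v = metrics[m]
            rows.append({
                "metric": m, "family": fam, "n": int(v.notna().sum()),
                "mean": v.mean(), "sd": v.std(ddof=1),
                "mean_male": v[sex == "male"].mean(),
                "mean_female": v[sex == "female"].mean(),
                "anova_p_across_instruments": p_anova,
            })
    tables["metrics_summary"] = pd.DataFrame(rows)

    # --- correlation matrix (metrics x metrics and metrics x outcomes)
    corr_input = pd.concat([metrics[mcols], outcome_df], axis=1)
    corr_input = corr_input.loc[:, ~corr_input.columns.duplicated()]
    r, p = spearman_matrix(corr_input.astype(float))
    corr_long = (
        r.stack().rename("spearman_r").to_frame()
        .join(p.stack().rename("p_value"))
        .reset_index(names=["var_a", "var_b"])
    )
    tables["correlations"] = corr_long[corr_long["var_a"] < corr_long["var_b"]]

    # --- concordance between the same metric from different instruments
    rows = []
    for fam, members in families.items():
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                sub = metrics[[a, b]].dropna()
                rows.append({
                    "metric_family": fam, "metric_a": a, "metric_b": b,
                    "n": len(sub),
                    "ccc": concordance_correlation(sub[a].to_numpy(), sub[b].to_numpy()),
                    "pearson_r": sub[a].corr(sub[b]),
                })
    tables["concordance"] = pd.DataFrame(rows)

    # --- Wolfe dependent-correlation tests: app score vs every other metric
    rows = []
    ref = "gdqs_app"
    out_cols = [c for c in outcome_df.columns]
    if ref in metrics.columns:
        for m in mcols:
            if m == ref:
                continue
            for oc in out_cols:
                sub = pd.concat([metrics[[ref, m]], outcome_df[[oc]]], axis=1).dropna()
                if len(sub) < 10:
                    continue
                res = wolfe_dependent_correlation_test(
                    sub[ref].to_numpy(), sub[m].to_numpy(),
                    sub[oc].to_numpy(dtype=float), names=(ref, m, oc))
                rows.append(dataclasses.asdict(res))
    tables["wolfe_tests"] = pd.DataFrame(rows)

    # --- quintile trend models and per-SD effects
    trend_rows, persd_rows = [], []
    for m in mcols:
        mv = metrics[m]
        for oc in out_cols:
            fam = "binary" if oc in config.binary_outcomes else "continuous"
            sub = pd.concat([mv.rename("metric"), outcome_df[oc].rename("y"), X],
                            axis=1).dropna()
            if len(sub) < 50 or sub["metric"].nunique() < 5:
                continue
            if fam == "binary" and sub["y"].nunique() < 2:
                continue
            q = assign_quintiles(sub["metric"].to_numpy())
            fit = fit_quintile_model(
                sub["y"].to_numpy(dtype=float), q,
                covariates=sub[list(config.covariates)],
                family=fam, metric=m, outcome_name=oc)
            row = {"metric": m, "outcome": oc, "family": fam, "n": fit.n,
                   "p_trend": fit.p_trend,
                   "trend_coefficient": fit.trend_coefficient,
                   "trend_variance": fit.trend_variance,
                   "converged": fit.converged}
            for _, qrow in fit.quintile_estimates.iterrows():
                k = int(qrow["quintile"])
                row[f"q{k}"] = qrow["estimate"]
                row[f"q{k}_lo"] = qrow["ci_low"]
                row[f"q{k}_hi"] = qrow["ci_high"]
            trend_rows.append(row)
            try:
                ps = per_sd_association(
                    sub["y"].to_numpy(dtype=float), sub["metric"].to_numpy(),
                    covariates=sub[list(config.covariates)],
                    family=fam, metric=m, outcome_name=oc)
                persd_rows.append(dataclasses.asdict(ps))
            except Exception as exc:  # pragma: no cover - separation etc.
                log.warning("per-SD fit failed for %s/%s: %s", m, oc, exc)
    tables["trend_models"] = pd.DataFrame(trend_rows)
    tables["per_sd"] = pd.DataFrame(persd_rows)

    # --- pairwise Wald comparisons of trends: app vs each other metric
    rows = []
    if config.pairwise and ref in metrics.columns:
        rng = np.random.default_rng([config.seed, 200])
        for oc in [c for c in config.pairwise_outcomes if c in outcome_df.columns]:
            fam = "binary" if oc in config.binary_outcomes else "continuous"
            for m in mcols:
                if m == ref:
                    continue
                sub = pd.concat([metrics[[ref, m]], outcome_df[[oc]], X],
                                axis=1).dropna()
                if len(sub) < 50:
                    continue
                res = wald_trend_difference(
                    sub[oc].to_numpy(dtype=float), sub[ref].to_numpy(),
                    sub[m].to_numpy(),
                    covariates=sub[list(config.covariates)], family=fam,
                    n_boot=config.n_boot, rng=rng, names=(ref, m, oc))
                rows.append(dataclasses.asdict(res))
    tables["pairwise_differences"] = pd.DataFrame(rows)

    # --- adequacy prevalence summaries (both readings of "% adequacy")
    prev_rows = []
    for label, adeq in adeq_tables.items():
        prev = prevalence_summary(adeq, [n for n in adeq.columns if n != "mpa"])
        prev.insert(0, "instrument", label)
        prev_rows.append(prev)
    tables["adequacy_summary"] = (
        pd.concat(prev_rows, ignore_index=True) if prev_rows else pd.DataFrame())

    log.info("statistics done (%.1fs)", time.time() - t0)
    if outdir is not None:
        manifest = build_manifest(config)
        write_report(tables, manifest, outdir)
    return tables


COLUMN_DICTIONARY = {
    "metrics_summary": "Per metric-instrument: mean/SD overall and by sex; ANOVA p across instruments within a metric family.",
    "correlations": "Pairwise-complete Spearman correlations among metrics and outcomes (long form).",
    "concordance": "Lin concordance correlation between the same metric from different instruments.",
    "wolfe_tests": "Dependent-correlation tests: app score vs another metric against a shared outcome.",
    "trend_models": "Covariate-adjusted quintile models: Q1-Q5 EMMs (continuous) or ORs vs Q1 (binary), trend coefficient/variance, p for linear trend.",
    "per_sd": "Association per 1 SD of the metric, same covariates.",
    "pairwise_differences": "Paired-bootstrap Wald tests of equal quintile trends: app vs other metrics.",
    "adequacy_summary": "Per nutrient: mean adequacy probability (%) and share of participants with probability > 0.5 (%).",
}


def build_manifest(config: RunConfig) -> dict:
    cfg = dataclasses.asdict(config)
    if config.sim is not None:
        cfg["sim"] = {"config_hash": config.sim.config_hash(),
                      "seed": config.sim.seed}
    blob = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "seed": config.seed,
        "software_version": __version__,
    }
    if config.include_timestamps:
        manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    return manifest


def write_report(
    tables: dict[str, pd.DataFrame], manifest: dict, outdir: str | Path,
    overwrite: bool = False,
) -> None:
    """Write report tables (full precision + display-rounded copy) and manifest.

    Refuses to write into a directory whose existing manifest has a different
    config hash unless *overwrite* is set; checks writability before any
    partial write.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mpath = outdir / "manifest.json"
    if mpath.exists() and not overwrite:
        with open(mpath) as fh:
            old = json.load(fh)
        if old.get("config_hash") not in (None, manifest["config_hash"]):
            raise RuntimeError(
                f"manifest checksum mismatch in {outdir}: existing run used config "
                f"{old.get('config_hash')}, this run is {manifest['config_hash']}; "
                "pass overwrite=True to replace it")
    probe = outdir / ".write_probe"
    probe.write_text("")
    probe.unlink()

    checksums = {}
    for name, df in tables.items():
        out = df.copy()
        path = outdir / f"{name}.csv"
        out.to_csv(path, index=False, float_format="%.10g")
        out.round(4).to_csv(outdir / f"{name}_rounded.csv", index=False)
        checksums[f"{name}.csv"] = hashlib.sha256(path.read_bytes()).hexdigest()
    pd.DataFrame(
        [{"table": k, "description": v} for k, v in COLUMN_DICTIONARY.items()]
    ).to_csv(outdir / "column_dictionary.csv", index=False)
    manifest = dict(manifest, checksums=checksums)
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
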