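"""Metric-comparison statistics: rank-correlation matrices, Lin's concordance,
dependent-correlation tests, covariate-adjusted quintile trend models, per-SD
effects, and paired-bootstrap Wald comparisons of trends between metrics.

The user-facing quintile and per-SD models are fit with statsmodels; the
bootstrap inside :func:`wald_trend_difference` uses an internal least-squares /
IRLS solver so that thousands of refits stay cheap.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger("dietmetrics")


# ---------------------------------------------------------------------------
# Correlation layer
# ---------------------------------------------------------------------------

def spearman_matrix(table: pd.DataFrame, min_n: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman rank correlations with p-values.

    Returns ``(r, p)`` symmetric frames with unit diagonal; mid-ranks for
    ties.  Pairs with fewer than *min_n* complete observations, or with a
    constant column, are reported missing.
    """
    cols = list(table.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            sub = table[[a, b]].astype(float).dropna()
            if len(sub) < min_n or sub[a].nunique() < 2 or sub[b].nunique() < 2:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            rs, pv = stats.spearmanr(sub[a], sub[b])
            r.loc[a, b] = r.loc[b, a] = rs
            p.loc[a, b] = p.loc[b, a] = pv
    return r, p


def concordance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient with population (1/n) moments.

    ``CCC = 2 s_xy / (s_x² + s_y² + (x̄ − ȳ)²)``; penalises location and
    scale disagreement, so |CCC| <= |Pearson r|.  Undefined (NaN) when both
    vectors are constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D vectors, n >= 3")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    sx2 = x.var()
    sy2 = y.var()
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0:
        return float("nan")
    return float(2.0 * sxy / denom)


@dataclass(frozen=True)
class CorrComparison:
    """Result of a test that two dependent correlations with a shared outcome are equal."""

    metric_a: str
    metric_b: str
    outcome: str
    r_a: float
    r_b: float
    n: int
    statistic: float
    p_value: float
    method: str = "wolfe_rank_difference"


def wolfe_dependent_correlation_test(
    x1: np.ndarray, x2: np.ndarray, y: np.ndarray,
    names: tuple[str, str, str] = ("x1", "x2", "y"),
) -> CorrComparison:
    """Test H0: ρ_s(x1, y) = ρ_s(x2, y) for two metrics measured on the same people.

    All three variables are rank-transformed (mid-ranks); the ranked metrics
    are standardized and differenced, ``d = z1 − z2``.  Under H0 (and
    exchangeability of the two metrics given y) d is uncorrelated with y, so
    the usual t-test of ``r(d, y)`` with n − 2 df applies.  Identical metrics
    give statistic 0, p = 1.  Cross-validated against a within-subject
    label-swap permutation oracle in the test suite.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x1) & np.isfinite(x2) & np.isfinite(y)
    x1, x2, y = x1[mask], x2[mask], y[mask]
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 complete triples")
    r_a = stats.spearmanr(x1, y).statistic
    r_b = stats.spearmanr(x2, y).statistic
    rz1 = _standardized_ranks(x1)
    rz2 = _standardized_ranks(x2)
    ry = _standardized_ranks(y)
    d = rz1 - rz2
    if np.std(d) == 0:
        return CorrComparison(*names[:2], names[2], r_a, r_b, n, 0.0, 1.0)
    r = float(np.corrcoef(d, ry)[0, 1])
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return CorrComparison(names[0], names[1], names[2], float(r_a), float(r_b),
                          n, float(t), float(p))


def _standardized_ranks(x: np.ndarray) -> np.ndarray:
    r = stats.rankdata(x, method="average")
    s = r.std()
    return (r - r.mean()) / s if s > 0 else np.zeros_like(r)


# ---------------------------------------------------------------------------
# Quintiles and trend models
# ---------------------------------------------------------------------------

def assign_quintiles(values: np.ndarray, n_groups: int = 5) -> np.ndarray:
    """Quintile labels 1..5 from mid-ranks: ``clip(ceil(5·midrank/n), 1, 5)``.

    Deterministic under ties (tied values share a label) and equivariant to
    permutation of the input order; group sizes differ by at most 1 when
    there are no ties.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} observations")
    ranks = stats.rankdata(values, method="average")
    return np.clip(np.ceil(n_groups * ranks / n).astype(int), 1, n_groups)


@dataclass
class TrendFit:
    """Quintile-model output: the row unit of the study's association tables."""

    metric: str
    outcome: str
    family: str                       # "continuous" | "binary"
    n: int
    quintile_estimates: pd.DataFrame  # quintile, estimate, ci_low, ci_high
    p_trend: float
    trend_coefficient: float
    trend_variance: float
    covariates: tuple[str, ...] = ()
    per_sd_estimate: float | None = None
    per_sd_ci: tuple[float, float] | None = None
    converged: bool = True
    diagnostic: str = ""


def _design(quintiles: np.ndarray, covariates: pd.DataFrame | None):
    """Q2..Q5 dummy design plus covariates, with an intercept."""
    q = pd.get_dummies(pd.Categorical(quintiles, categories=[1, 2, 3, 4, 5]),
                       prefix="q", dtype=float).iloc[:, 1:]
    X = q
    if covariates is not None:
        X = pd.concat([q.reset_index(drop=True),
                       covariates.reset_index(drop=True).astype(float)], axis=1)
    return sm.add_constant(X, has_constant="add")


def fit_quintile_model(
    outcome: np.ndarray,
    quintiles: np.ndarray,
    covariates: pd.DataFrame | None = None,
    family: str = "continuous",
    metric: str = "metric",
    outcome_name: str = "outcome",
    quintile_scores: Mapping[int, float] | None = None,
) -> TrendFit:
    """Covariate-adjusted quintile model with a linear-trend test.

    Continuous outcomes: least squares; the per-quintile estimates are
    estimated marginal means — the model prediction for each quintile with
    every covariate fixed at its sample mean (for 0/1-coded categorical
    covariates the mean is the observed category proportion).  Binary
    outcomes: logistic regression; estimates are odds ratios against
    quintile 1 (Q1 OR = 1 by construction).  The trend p-value comes from
    refitting with the quintile entered as a single ordinal score (1..5 by
    default; pass *quintile_scores* — e.g. quintile medians — to change the
    coding); the trend coefficient and its variance are stored for Wald
    comparisons between metrics.
    """
    if family not in ("continuous", "binary"):
        raise ValueError("family must be 'continuous' or 'binary'")
    y = np.asarray(outcome, dtype=float)
    q = np.asarray(quintiles)
    mask = np.isfinite(y)
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
        mask &= covariates.notna().all(axis=1).to_numpy()
        covariates = covariates.loc[mask].reset_index(drop=True)
    y, q = y[mask], q[mask]
    n = len(y)
    X = _design(q, covariates)
    scores = np.array([float((quintile_scores or {}).get(k, k)) for k in q])
    Xt = pd.DataFrame({"trend": scores})
    if covariates is not None:
        Xt = pd.concat([Xt, covariates.astype(float)], axis=1)
    Xt = sm.add_constant(Xt, has_constant="add")

    covnames = tuple(covariates.columns) if covariates is not None else ()
    try:
        if family == "continuous":
            res = sm.OLS(y, X).fit()
            rest = sm.OLS(y, Xt).fit()
        else:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            rest = sm.Logit(y, Xt).fit(disp=0, maxiter=200)
            if not (res.mle_retvals["converged"] and rest.mle_retvals["converged"]):
                raise sm.tools.sm_exceptions.ConvergenceWarning("logit did not converge")
    except Exception as exc:  # separation / convergence failure
        return TrendFit(metric, outcome_name, family, n,
                        pd.DataFrame(columns=["quintile", "estimate", "ci_low", "ci_high"]),
                        np.nan, np.nan, np.nan, covnames,
                        converged=False, diagnostic=str(exc))

    qcols = [f"q_{k}" for k in (2, 3, 4, 5)]
    if family == "continuous":
        # EMM: prediction at each quintile, covariates at sample means
        base = X.mean(axis=0)
        rows = []
        for k in (1, 2, 3, 4, 5):
            L = base.copy()
            for c in qcols:
                L[c] = 1.0 if c == f"q_{k}" else 0.0
            est = float(L @ res.params)
            se = float(np.sqrt(L @ res.cov_params() @ L))
            rows.append({"quintile": k, "estimate": est,
                         "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se})
    else:
        rows = [{"quintile": 1, "estimate": 1.0, "ci_low": np.nan, "ci_high": np.nan}]
        for k in (2, 3, 4, 5):
            b = res.params[f"q_{k}"]
            se = res.bse[f"q_{k}"]
            rows.append({"quintile": k, "estimate": float(np.exp(b)),
                         "ci_low": float(np.exp(b - 1.96 * se)),
                         "ci_high": float(np.exp(b + 1.96 * se))})
    return TrendFit(
        metric=metric, outcome=outcome_name, family=family, n=n,
        quintile_estimates=pd.DataFrame(rows),
        p_trend=float(rest.pvalues["trend"]),
        trend_coefficient=float(rest.params["trend"]),
        trend_variance=float(rest.cov_params().loc["trend", "trend"]),
        covariates=covnames,
    )


@dataclass(frozen=True)
class PerSDResult:
    metric: str
    outcome: str
    family: str
    estimate: float          # slope per 1 SD (continuous) or log-OR per 1 SD (binary)
    ci_low: float
    ci_high: float
    p_value: float
    sd_unit: float
    n: int


def per_sd_association(
    outcome: np.ndarray,
    metric_values: np.ndarray,
    covariates: pd.DataFrame | None = None,
    family: str = "continuous",
    metric: str = "metric",
    outcome_name: str = "outcome",
) -> PerSDResult:
    """Association per 1-SD difference in the metric, with the same covariates.

    The metric is divided by its sample SD, so the estimate is unchanged by
    any rescaling of metric units.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(metric_values, dtype=float)
    mask = np.isfinite(y) & np.isfinite(x)
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
        mask &= covariates.notna().all(axis=1).to_numpy()
        covariates = covariates.loc[mask].reset_index(drop=True)
    y, x = y[mask], x[mask]
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("metric SD is zero")
    X = pd.DataFrame({"metric_sd": x / sd})
    if covariates is not None:
        X = pd.concat([X, covariates.astype(float)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    if family == "continuous":
        res = sm.OLS(y, X).fit()
    else:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    b = float(res.params["metric_sd"])
    se = float(res.bse["metric_sd"])
    return PerSDResult(metric, outcome_name, family, b,
                       b - 1.96 * se, b + 1.96 * se,
                       float(res.pvalues["metric_sd"]), sd, len(y))


# ---------------------------------------------------------------------------
# Paired-bootstrap Wald comparison of trends
# ---------------------------------------------------------------------------

def _fast_trend_coef(y, x_trend, covariates, family) -> tuple[float, bool]:
    """Trend coefficient from a small in-house fit (OLS or IRLS logistic)."""
    n = len(y)
    if covariates is not None and covariates.size:
        X = np.column_stack([np.ones(n), x_trend, covariates])
    else:
        X = np.column_stack([np.ones(n), x_trend])
    if family == "continuous":
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(beta[1]), True
    # IRLS for logistic regression
    beta = np.zeros(X.shape[1])
    for _ in range(25):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        except np.linalg.LinAlgError:
            return float("nan"), False
        if not np.all(np.isfinite(beta_new)):
            return float("nan"), False
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            return float(beta[1]), True
        beta = beta_new
    return float(beta[1]), bool(np.max(np.abs(beta)) < 50)


@dataclass(frozen=True)
class WaldComparison:
    """Paired-bootstrap Wald test of equal quintile trends for two metrics."""

    metric_a: str
    metric_b: str
    outcome: str
    trend_a: float
    trend_b: float
    delta: float
    var_delta: float
    z: float
    p_value: float
    n_boot: int
    nonconverged_fraction: float = 0.0
    warning: str = ""


def wald_trend_difference(
    outcome: np.ndarray,
    metric_a: np.ndarray,
    metric_b: np.ndarray,
    covariates: pd.DataFrame | None = None,
    family: str = "continuous",
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
    names: tuple[str, str, str] = ("metric_a", "metric_b", "outcome"),
) -> WaldComparison:
    """Wald test of Δ = trend_a − trend_b using a paired nonparametric bootstrap.

    Both metrics are measured on the same participants, so the two trend
    estimates are dependent; resampling participants jointly (quintiles
    reassigned within each resample) captures that dependence without model
    assumptions.  ``z = Δ/√Var_boot(Δ)``, two-sided normal p.  Identical
    metrics give Δ = 0, p = 1.
    """
    rng = np.random.default_rng(rng)
    y = np.asarray(outcome, dtype=float)
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    mask = np.isfinite(y) & np.isfinite(a) & np.isfinite(b)
    C = None
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
        mask &= covariates.notna().all(axis=1).to_numpy()
        C = covariates.loc[mask].to_numpy(dtype=float)
    y, a, b = y[mask], a[mask], b[mask]
    n = len(y)

    def trends(yv, av, bv, Cv):
        qa = assign_quintiles(av).astype(float)
        qb = assign_quintiles(bv).astype(float)
        ta, oka = _fast_trend_coef(yv, qa, Cv, family)
        tb, okb = _fast_trend_coef(yv, qb, Cv, family)
        return ta, tb, oka and okb

    t_a, t_b, ok = trends(y, a, b, C)
    if np.array_equal(a, b):
        return WaldComparison(*names[:2], names[2], t_a, t_b, 0.0, 0.0, 0.0, 1.0, 0)
    deltas = np.empty(n_boot)
    failed = 0
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        ta, tb, okb = trends(y[idx], a[idx], b[idx], C[idx] if C is not None else None)
        if okb and np.isfinite(ta) and np.isfinite(tb):
            deltas[i] = ta - tb
        else:
            deltas[i] = np.nan
            failed += 1
    frac_fail = failed / n_boot
    good = deltas[np.isfinite(deltas)]
    warning = ""
    if frac_fail > 0.05:
        warning = f"bootstrap non-convergence fraction {frac_fail:.1%} exceeds 5%"
        log.warning(warning)
    delta = t_a - t_b
    var = float(np.var(good, ddof=1)) if len(good) > 1 else float("nan")
    if delta == 0.0 and (var == 0.0 or not np.isfinite(var)):
        z, p = 0.0, 1.0
    elif var == 0 or not np.isfinite(var):
        z, p = np.nan, np.nan
    else:
        z = delta / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return WaldComparison(names[0], names[1], names[2], t_a, t_b, delta, var,
                          float(z), float(p), n_boot, frac_fail, warning)
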