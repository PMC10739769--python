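"""Usual nutrient intake from replicate recall days, and residual energy adjustment.

Replicate 24-h recalls measure one day, not habitual diet: the observed
between-person variance is inflated by within-person day-to-day variance.
This module removes that inflation with a one-part Box-Cox/shrinkage model:

1. transform daily intakes to approximate normality (Box-Cox, λ on a grid);
2. partition variance into between- (σ²_b) and within-person (σ²_w)
   components by method of moments;
3. shrink person means toward the grand mean by
   ``S = σ²_b / (σ²_b + σ²_w / k)`` (k replicate days);
4. back-transform with a second-order Taylor bias correction.

This is a deliberately simple one-part analogue of measurement-error models
used for daily-consumed nutrients; it does not model episodic consumption or
covariates (see the package methods note).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("dietmetrics")

LAMBDA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


@dataclass(frozen=True)
class VarianceComponents:
    """Variance decomposition of one nutrient on its transformed scale."""

    nutrient: str
    lambda_boxcox: float
    sigma2_between: float
    sigma2_within: float
    k_days: float
    grand_mean_transformed: float

    def __post_init__(self):
        if self.sigma2_between < 0 or self.sigma2_within < 0 or self.k_days < 1:
            raise ValueError("invalid variance components")

    @property
    def shrinkage(self) -> float:
        denom = self.sigma2_between + self.sigma2_within / self.k_days
        return 1.0 if denom == 0 else self.sigma2_between / denom


def boxcox_transform(x: np.ndarray, lam: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    return np.log(x) if lam == 0 else (x ** lam - 1.0) / lam


def boxcox_inverse(z: np.ndarray, lam: float) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if lam == 0:
        return np.exp(z)
    return np.maximum(lam * z + 1.0, 0.0) ** (1.0 / lam)


def select_boxcox_lambda(values: np.ndarray, grid=LAMBDA_GRID) -> float:
    """λ from the grid maximizing the Box-Cox normal log-likelihood (λ=0 is log).

    The likelihood includes the Jacobian term, so the choice is invariant to
    rescaling the intakes (kcal vs kJ, mg vs µg).
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if np.sum(values > 0) < 10:
        raise ValueError("need at least 10 positive observations to select lambda")
    if np.any(values <= 0):
        raise ValueError("values must be positive (apply a zero offset first)")
    lls = [stats.boxcox_llf(lam, values) for lam in grid]
    return float(grid[int(np.argmax(lls))])


def apply_zero_offset(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Replace zeros by half the smallest positive value; returns (values, offset)."""
    values = np.asarray(values, dtype=float)
    if not np.any(values == 0):
        return values, 0.0
    pos = values[values > 0]
    if len(pos) == 0:
        raise ValueError("all values are zero; nothing to transform")
    offset = 0.5 * pos.min()
    log.info("zero offset %.4g applied to %d zero intakes", offset, int((values == 0).sum()))
    out = values.copy()
    out[out == 0] = offset
    return out, offset


def estimate_variance_components(
    transformed: np.ndarray,
    person_ids: np.ndarray,
    nutrient: str = "",
    lam: float = 1.0,
) -> VarianceComponents:
    """Method-of-moments variance decomposition from replicate days.

    σ²_w is the pooled within-person sample variance; σ²_b is
    ``var(person means) − σ²_w / k`` truncated at 0, with k the mean number of
    replicate days per person.  Requires at least some participants with ≥ 2
    days.
    """
    df = pd.DataFrame({"person": person_ids, "y": np.asarray(transformed, dtype=float)})
    df = df.dropna()
    g = df.groupby("person")["y"]
    counts = g.count()
    if (counts < 2).all():
        raise ValueError("no participant has >= 2 days; within-person variance inestimable")
    within = g.var(ddof=1)          # NaN for single-day persons
    k = float(counts.mean())
    sigma2_w = float(np.average(within.dropna(), weights=(counts - 1)[within.notna()]))
    means = g.mean()
    var_means = float(means.var(ddof=1))
    sigma2_b = max(0.0, var_means - sigma2_w / k)
    return VarianceComponents(
        nutrient=nutrient, lambda_boxcox=lam,
        sigma2_between=sigma2_b, sigma2_within=sigma2_w,
        k_days=k, grand_mean_transformed=float(df["y"].mean()),
    )


def estimate_usual_intake(
    transformed: np.ndarray,
    person_ids: np.ndarray,
    comps: VarianceComponents,
) -> pd.Series:
    """Per-person usual intake on the original scale.

    On the transformed scale the person mean is shrunk toward the grand mean
    by ``S = σ²_b / (σ²_b + σ²_w/k)``; the back-transform adds the
    second-order correction ``½ g⁻¹''(x) · v`` with ``v = S·σ²_w/k``, the
    residual (posterior) variance of the usual value about its estimate.
    """
    df = pd.DataFrame({"person": person_ids, "y": np.asarray(transformed, dtype=float)})
    means = df.dropna().groupby("person")["y"].mean()
    S = comps.shrinkage
    mu = comps.grand_mean_transformed
    shrunk = mu + S * (means - mu)
    v = S * comps.sigma2_within / comps.k_days
    lam = comps.lambda_boxcox
    z = shrunk.to_numpy()
    if v == 0 or lam == 1:
        second = np.zeros_like(z)
    elif lam == 0:
        second = np.exp(z)
    else:
        with np.errstate(divide="ignore"):
            base = np.maximum(lam * z + 1.0, 0.0)
            second = (1.0 - lam) * base ** (1.0 / lam - 2.0)
        second = np.where(np.isfinite(second), second, 0.0)
    usual = boxcox_inverse(z, lam) + 0.5 * second * v
    usual = np.maximum(usual, 0.0)
    return pd.Series(usual, index=means.index, name=comps.nutrient or "usual")


def energy_adjust_residual(intake: np.ndarray, energy: np.ndarray) -> np.ndarray:
    """Residual-method energy adjustment.

    Fits ``intake = a + b·energy`` by least squares and returns
    ``residual + (a + b·mean(energy))`` — the intake each person would have at
    the population mean energy.  The mean of the adjusted vector equals the
    mean of the input; the result is invariant to affine rescaling of energy
    units.  Zero energy variance skips adjustment with a warning.
    """
    intake = np.asarray(intake, dtype=float)
    energy = np.asarray(energy, dtype=float)
    if intake.shape != energy.shape or intake.ndim != 1 or len(intake) < 3:
        raise ValueError("intake and energy must be equal-length 1-D vectors, n >= 3")
    if np.var(energy) == 0:
        log.warning("energy variance is zero; residual adjustment skipped")
        return intake.copy()
    b, a = np.polyfit(energy, intake, 1)
    resid = intake - (a + b * energy)
    adjusted = resid + (a + b * energy.mean())
    n_neg = int((adjusted < 0).sum())
    if n_neg:
        log.warning("residual adjustment floored %d negative values at 0", n_neg)
        adjusted = np.maximum(adjusted, 0.0)
    return adjusted


def usual_intake_table(
    daily_nutrients: pd.DataFrame,
    nutrients: list[str],
    energy_col: str = "energy_kcal",
    shrink: bool = True,
) -> pd.DataFrame:
    """UsualIntakeTable for one instrument: usual and energy-adjusted usual intakes.

    *daily_nutrients* is the output of ``study_io.compute_daily_nutrients``
    restricted to one instrument.  With ``shrink=True`` (the 24HR pathway)
    each nutrient goes through Box-Cox selection, variance decomposition, and
    shrinkage; with ``shrink=False`` (the FFQ pathway, which already targets
    habitual intake) person means are used directly.  Energy adjustment is by
    the residual method against usual energy.
    """
    persons = daily_nutrients["participant_id"].to_numpy()
    cols = {}
    for nut in [energy_col] + [n for n in nutrients if n != energy_col]:
        vals = daily_nutrients[nut].to_numpy(dtype=float)
        mask = np.isfinite(vals)
        if shrink:
            pos, _ = apply_zero_offset(vals[mask])
            lam = select_boxcox_lambda(pos)
            z = boxcox_transform(pos, lam)
            comps = estimate_variance_components(z, persons[mask], nutrient=nut, lam=lam)
            cols[nut] = estimate_usual_intake(z, persons[mask], comps)
        else:
            cols[nut] = (
                pd.Series(vals[mask], index=persons[mask]).groupby(level=0).mean()
            )
    usual = pd.DataFrame(cols)
    usual.index.name = "participant_id"
    adjusted = usual.copy()
    energy = usual[energy_col].to_numpy()
    for nut in nutrients:
        if nut == energy_col:
            continue
        adjusted[nut] = energy_adjust_residual(usual[nut].to_numpy(), energy)
    long = usual.reset_index().melt(
        id_vars="participant_id", var_name="nutrient", value_name="usual")
    long_adj = adjusted.reset_index().melt(
        id_vars="participant_id", var_name="nutrient", value_name="usual_energy_adjusted")
    return long.merge(long_adj, on=["participant_id", "nutrient"])
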