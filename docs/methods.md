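# Methods notes

This note records the models, numerical choices, and defaults behind
`dietmetrics`, and what the synthetic-data tests do and do not demonstrate.

## Metric scoring

**GDQS.** Each food group has ordered gram cut-offs defining consumption
categories and per-category points. Categories are half-open `[lower, upper)`
with the final category unbounded, so grams exactly at a cut-off fall
upward — one convention had to be fixed, and this mirrors the MDDW
"met or exceeded" rule. Healthy-group points accumulate into GDQS+, the
rest into GDQS−; the total is their sum. The packaged table
(`data/gdqs_table.csv`, 25 groups, maximum 49 points) is an editable
transcription of the published cut-offs; the unit tests exercise a toy
three-group table printed in the test code, so scoring correctness never
rests on the transcription.

**Cube quantizer (app pathway).** The app estimates group-level portions
with 10 reference cubes. We model a reported portion as the representable
volume — any multiset of cubes with each cube used at most
`max_multiplicity` times (default 2) — nearest to the true volume, ties
toward the smaller; a per-group density converts grams to millilitres.
Neither the fielded cube volumes nor their combination semantics are
public, so the whole geometry sits in `data/cubes.yaml`. The quantizer is
verified against brute-force enumeration of all cube multisets, and its
error is bounded by half the largest gap between adjacent representable
sums (within the representable range).

**MDDW** counts 10 food groups at the ≥ 15 g threshold; we report both the
0–10 count (used for quintiles) and the ≥ 5 binary indicator.

**AHEI-2010** components are linear interpolations between a 0-point and a
10-point anchor, clipped to [0, 10]; gram-to-serving conversions are
config-driven defaults, not asserted study values. The default config
scores 9 food-group components plus the sodium component proxied by the
0–100 sodium screener (`10·(1 − score/100)`); alcohol and trans-fat are not
derivable from group-level gram intakes and are omitted unless the user
supplies them as extra components. A participant missing the screener gets
a missing total unless partial totals are enabled.

**GDR** uses sentinel-food dichotomous scoring on the recall day: a group
is consumed if any member food has grams > 0. The default taxonomy maps 9
encouraged and 8 limit groups onto the packaged group list and is editable.

**Sodium screener**: `100 · Σ wᵢxᵢ / Σ wᵢxᵢᵐᵃˣ` over 12 frequency and 10
habit items, giving a 0–100 range by construction.

## Usual intakes

Replicate 24-h recalls inflate between-person variance with day-to-day
noise. We remove it with a deliberately simple one-part model:

1. zeros offset by half the smallest positive observation;
2. Box-Cox λ selected from {0, 0.1, …, 1} by maximizing the normal
   log-likelihood including the Jacobian (hence scale-invariant; λ = 0 is
   the log);
3. method-of-moments decomposition: σ²_w is the pooled within-person
   variance, σ²_b = max(0, var(person means) − σ²_w/k);
4. person means shrunk toward the grand mean by
   S = σ²_b/(σ²_b + σ²_w/k);
5. back-transform with the second-order correction
   g⁻¹(x) + ½·g⁻¹''(x)·v, where v = S·σ²_w/k is the posterior variance of
   the usual value about its estimate. Negative back-transformed values are
   floored at zero with a warning counter.

This is a one-part analogue of measurement-error ("usual intake") models:
it does not model episodic consumption (two-part likelihoods), covariates,
or nuisance day effects, which is adequate for daily-consumed nutrients and
keeps the estimator closed-form. The interface isolates the step so a full
mixed-model implementation can drop in.

FFQ intakes already target habitual diet and are not shrunk — person means
are used directly.

**Energy adjustment** is the residual method: regress intake on energy,
keep the residual plus the intake predicted at mean energy. Means are
preserved; the result is invariant to affine rescaling of energy units.
Adjustment is applied after shrinkage for the 24HR pathway and directly to
FFQ person means.

## Adequacy

The full-probability method with a normal requirement distribution:
P(adequate) = Φ((intake − EAR)/(EAR·CV)); per-kg requirements (protein)
scale the EAR by body weight first. The skewed-requirement refinement
sometimes used for iron in menstruating women is intentionally omitted —
the requirement inputs here are CV-parameterized throughout — and the spec
of the requirement distribution is a per-nutrient config, so it can be
replaced. MPA is the unweighted arithmetic mean over exactly six
micronutrient probabilities; any missing component makes MPA missing
(no renormalization) unless pairwise averaging is requested. Energy-adjusted
adequacy feeds residual-adjusted usual intakes into the same formula;
requirements are not energy-scaled. Population "% adequacy" is reported
under both readings — mean probability, and share with probability > 0.5 —
since the two differ whenever the probability distribution is asymmetric.

## Outcomes

Cut-offs follow WHO/IDF conventions for this population: BMI classes with
[18.5, 25] healthy (25.0 is healthy; the `overweight_or_obese` flag is
BMI ≥ 25 as its name is conventionally defined), WC ≥ 90/80 cm (M/F),
WHtR > 0.5, MUAC ≥ 30.9/30.0 cm, BP ≥ 130/85 or medication, Hb < 130/120
g/L, TG > 150, HDL < 40/50, LDL > 160, FPG ≥ 100, HbA1c > 6.5 %. MetS uses
the IDF gate: abdominal obesity mandatory plus ≥ 2 of the other four
components. Missing inputs make the corresponding flag missing without
failing the rest; sex-dependent flags are missing when sex is.

## Comparison statistics

**Dependent-correlation test.** To compare ρ(x₁, y) with ρ(x₂, y) when all
three are measured on the same people: rank-transform everything,
standardize the ranked metrics, difference them (d = z₁ − z₂), and t-test
the correlation of d with the ranked outcome (n − 2 df). Under the null
with exchangeable metrics, cov(d, y) = 0. The binding contract is
agreement with a within-subject label-swap permutation oracle, which the
test suite checks on exchangeable datasets — the permutation null *is*
exchangeability, so that is the regime where oracle agreement is
well-defined; under unequal true correlations the two procedures answer
slightly different questions. Empirical size at n = 600 is checked over
2000 replicates.

**Quintile models.** Quintiles come from mid-ranks
(`clip(ceil(5·rank/n), 1, 5)`), deterministic under ties. Continuous
outcomes use least squares with quintile dummies; the per-quintile
estimated marginal mean fixes every covariate at its sample mean (for 0/1
dummies that is the observed category proportion) — one standard reference
grid. Binary outcomes use logistic regression with odds ratios against
quintile 1. Trend p-values come from refitting with the quintile as a
single ordinal score 1–5 (quintile-median scoring is available via
`quintile_scores`); the trend coefficient and variance are retained for
between-metric comparisons. Logistic separation or non-convergence is
reported as a non-converged fit with the diagnostic, never silently.

**Per-SD effects** rescale the metric by its sample SD, making estimates
invariant to metric units.

**Between-metric Wald comparison.** Δ = trend_a − trend_b with variance
from a paired nonparametric bootstrap (participants resampled jointly,
quintiles reassigned within each resample; default B = 1000, seeded). The
paired bootstrap captures the same-sample dependence between the two trend
estimates without extra model assumptions. Bootstrap refits use an
internal closed-form OLS / IRLS-logistic solver for speed; the module test
verifies it matches statsmodels on the point estimate. A non-convergence
fraction above 5 % attaches a warning.

No multiple-testing adjustment is applied anywhere; p-values are reported
raw.

## Synthetic study generator

A single latent factor L ~ N(0,1) stands in for "diet quality". Each food
group's usual log-intake is `μ_g + λ_g·L + N(0, σ_b)`; each day adds
`N(0, σ_w)` and a per-day consumption probability (unhealthy groups are
not eaten daily by everyone). The 24HR reports food-level grams with
multiplicative lognormal error (SD 0.15); the app reports the same day's
group totals through the cube quantizer; the FFQ reports usual intake with
its own lognormal error (SD 0.35) and a systematic ×1.2 scale, which
reproduces FFQ-derived scores exceeding recall-derived ones. Clinical
outcomes are linear or logistic in L with signs chosen to mimic a
protective diet-quality factor (positive loadings for HDL and urinary
potassium, negative for adiposity, diastolic BP, and the salt screener);
magnitudes are calibrated to the quintile spans such validation studies
report (e.g. ~4 mg/dL HDL and ~260 mg urinary K across quintiles) and are
illustrative, not estimates. Covariates carry a mild correlation with L
(confounding), switchable off. `SimConfig.null()` zeroes every diet and
outcome loading for calibration experiments.

Defaults encode the emulated design: n = 600, 75.6 % female, ages 40–60,
2 recall days, ~25 % institutional staff. The food catalog is fully
synthetic (two foods per group at fixed 65/35 shares), with micronutrients
concentrated in healthy groups and composition values shaped so usual
intakes sit near requirement levels for most micronutrients (calcium
deliberately far below, matching the epidemiology of low-dairy diets) —
that keeps MPA responsive to L.

What passing tests show: the pipeline's algebra and statistics behave
correctly on data with the assumed structure (single latent factor,
lognormal intakes, independent instrument errors). What they do not show:
performance under real dietary data features the generator omits —
correlated food substitutions, differential misreporting by adiposity,
intake-requirement correlation, instrument order effects, or a real food
composition table.

## Problem sizes and numerical choices

Monte-Carlo checks run at the design sizes of the emulated study where the
property is about that design (n = 600, 2 days; dependent-correlation size
over 2000 replicates; trend-test null over 1000 replicates; odds-ratio
recovery over 200; variance-component recovery over 50; sign pattern over
20 seeded end-to-end studies; null false-positive share pooled over 10
studies). Module-level tests run lighter versions of the same simulations
(a few hundred replicates, bootstrap B = 200) as smoke-level guards; the
permutation oracle uses 20 000 permutations in the agreement check so its
own Monte-Carlo error is negligible relative to the 0.02 agreement band.
In the null-calibration experiments, metric-outcome pairs that are
structurally linked by construction are excluded from the false-positive
count: adequacy outcomes are computed from the same consumption records as
the metrics, and the sodium screener supplies the AHEI sodium component,
so neither is null even with all loadings zeroed.

Report tables are written with a fixed column order and `%.10g` floats
(plus a rounded display copy), so a rerun with the same config and seed is
byte-identical; the run manifest therefore omits timestamps by default
(`include_timestamps=True` restores them at the cost of reproducible
manifests). Degenerate inputs are handled explicitly: zero energy variance
skips adjustment with a warning; identical metrics give a zero statistic
and p = 1 in both the dependent-correlation and Wald comparisons; constant
columns yield missing correlations rather than errors.

## Known limitations

* The one-part usual-intake model understates uncertainty for episodically
  consumed foods and ignores covariate-dependent usual-intake
  distributions.
* Packaged scoring tables (GDQS cut-offs, AHEI servings, GDR taxonomy,
  requirement EARs/CVs) are editable best-effort defaults; analyses of real
  data must substitute authoritative tables.
* The EMM reference grid (covariates at sample means) is one convention;
  marginal standardization would differ for logistic models.
* No survey weights, no imputation (complete-case throughout, logged).
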