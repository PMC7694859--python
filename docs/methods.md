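# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the known limitations of `echoref`.

## Allometric model and prediction intervals

Each M-mode dimension Y (cm) is modeled as Y = a·BW^b with multiplicative
lognormal error: log Y = log a + b·log BW + ε, ε ~ N(0, σ²), fitted by
ordinary least squares on natural logs (a and b are invariant to the log
base once back-transformed consistently). σ is the residual SD with
n − 2 degrees of freedom; t is the two-sided Student-t quantile at the
95% level with the same df.

Two interval forms are exposed:

* **exact**: log Ŷ ± t·σ·√(1 + 1/n + (log BW − x̄)²/Sxx), back-transformed.
  The fit object stores x̄ and Sxx so the leverage term can be evaluated
  at any new weight.
* **approx**: log Ŷ ± t·σ, i.e. bounds a·e^(∓tσ)·BW^b. This is the
  "indexing constant" form used for on-the-spot calculation; at screening
  sample sizes (thousands of dogs) it differs from the exact interval by
  well under 1% anywhere in the 2–75 kg range (tested).

Percentile indexing constants are, by default, *empirical* percentiles of
the index Y/BW^b over the cohort, using linear interpolation between
order statistics (numpy's default, "type 7"). This matches the percentile
labelling of published constant tables and is robust to non-normal log
residuals. A parametric variant a·e^(z_p·σ) is available
(`parametric=True`); the two agree under lognormality (tested at n=50,000
to within 1%).

Fractional shortening FS = 100·(LVDd − LVDs)/LVDd carries almost no
weight information (R² ≈ 0.04, slope ≈ −0.065 on the log-log scale).
`weight_independent_cutoff` fits the allometric model first and, when
R² < 0.1, reports the empirical 5th percentile of the raw values instead
of a weight-dependent band. The 0.1 gate cleanly separates FS (≈0.04)
from the dimensional variables (≥0.46) and is configurable.

Printed reference tables round half-up to 0.1 cm, the precision of
published tables. When regenerating a published table from constants that
are themselves printed at two decimals, a value lying within the
constants' propagated precision (±0.005·BW^b ≈ ±0.01 cm) of a 0.05
rounding boundary can legitimately round the other way; the tests treat
exactly such cells as boundary-tolerant and accept no other disagreement.

## Outlier screening

Tukey-style far-out fences: values outside (Q1 − 3·IQR, Q3 + 3·IQR) are
flagged, computed separately per breed stratum. Breeds with at least 50
dogs form their own stratum; all smaller breeds are pooled into one
stratum so no record goes unscreened. Dimensional variables are screened
on the natural-log scale (their error is multiplicative); FS is screened
untransformed. A flagged value is set missing — the dog is kept for its
other variables. At k = 3 on clean lognormal data the false-positive rate
is below 0.5% and re-screening removes nothing new (both tested).

## Linearity validation (P-spline GAM)

The adequacy of the power law is checked by fitting y = s(BW^b) with a
penalized spline on the original scale and comparing the smooth to the
OLS straight line in BW^b. The smoother is a cubic B-spline basis on 20
equally spaced interior knots with a second-order difference penalty
(Eilers–Marx); λ is chosen by GCV = n·RSS/(n − edf)² over a 31-point
log-spaced grid 10⁻⁴…10⁶, ties going to the smaller λ; edf is the trace
of the smoother matrix. The second-order penalty's null space is the
straight line, so a truly linear signal is reproduced exactly at any λ
and the check cannot false-alarm on perfect data (tested to machine
precision).

"Visual inspection" of linearity is operationalized as: maximum
|smooth − line| over the central 98% of the predictor span, divided by
the fitted range, below 2%. The threshold is configurable; 2% is tight
enough to catch a 0.1·(log BW)² curvature term at cohort sizes of a few
thousand (tested) while passing power-law truth.

On the default synthetic cohort the wall/septal variables can exceed the
2% threshold even though each breed follows a power law: the deviant
Newfoundland multiplier bends the *mixture* away from a single power law
at the heavy end. That is a real feature of such screening populations
and exactly the misfit the diagnostic exists to surface; a cohort with
all multipliers at 1.0 passes for every variable.

Group comparison (all vs immaculate health classes) reports the mean
difference between the groups' exact upper PI limits over a BW grid, plus
an additive-model group effect (group indicator + shared P-spline in BW).
No p-value is reported: the question is the size of the difference, and
the observed value on same-truth groups is below 2% of the limit.

## Breed deviance

For each breed × variable the package counts strict exceedances of the
unrounded population PI bounds evaluated at each dog's own weight;
percentages are rounded to one decimal and a side is deviant when its
percentage strictly exceeds 10.0. Dogs missing a measurement leave that
variable's denominator. The population fits are the all-nonsighthound
ones, applied to every breed including sighthounds — deviance is defined
*relative to the general population*, which is why sighthound chambers
flag high and a Newfoundland-like breed flags low.

## Interobserver variability (RVa)

RVa = 100·τ²/(τ² + σ²_res), where τ² is the variance of a random examiner
intercept and σ²_res the remaining residual variance, both on the log
scale (making RVa invariant to units). Estimation is two-stage: (1) the
body-weight trend is removed from log Y by a GCV-selected P-spline in
log BW; (2) a one-way random-intercept model is fitted to the residuals
by REML (statsmodels `MixedLM`; unbalanced group sizes allowed, the
optimizer's parameterization keeps variances nonnegative). The analysis
is restricted to a single breed — by default the largest — so examiner
case-mix is not confounded with breed differences. The two-stage shortcut
is justified because examiner assignment is unrelated to body weight at
screening scale; the tests verify agreement with the closed-form one-way
ANOVA estimator to within one point and recovery of a known 1:3 variance
ratio.

Note on recovery experiments: with k examiners the *realized* examiner
variance is a scaled χ²_{k−1} draw; at k = 40 that alone gives the RVa
estimate a spread of ~4 points. Recovery is therefore assessed on the
mean over five replicate cohorts, which isolates estimator accuracy from
the luck of the draw.

## The synthetic cohort generator

The generator is the exact inverse of the analysis model, so every
pipeline stage has a known truth to recover:

* **Breed table** — 14 breeds with the sample sizes of a large
  multicenter screening database (Boxer 3111, Great Dane 900, Irish
  Wolfhound 837, … Whippet 47; ~6,900 dogs, ~5,400 nonsighthound). Breed
  BW medians are plausible breed-standard values (Boxer 30 kg, CKCS 8 kg,
  Great Dane 60 kg, …) — per-breed weight summaries are not published
  with the reference constants, so these are documented placeholders, not
  reproductions. Within-breed BW is lognormal (log-SD 0.10), truncated to
  1–90 kg, recorded to 0.1 kg.
* **Dimensions** — log Y = log(m·a) + b·log BW + u + ε with the published
  all-nonsighthound coefficients as truth (LVDd: a = 1.38, b = 0.322, …).
  σ per variable is calibrated so the implied 97.5th-percentile indexing
  constant matches the published one: σ = ln(c₉₇.₅/c₅₀)/1.96 (LVDd
  ≈ 0.0850, LVWd ≈ 0.1436).
* **Examiner effect** — u is a per-(examiner, variable) intercept,
  N(0, τ²) with τ = 0.05 over a pool of 48 examiners, which puts the
  implied RVa between ~9% and ~26% across variables, inside the
  8.1–30.6% range reported for real screening data.
* **FS** — computed from the generated LVDd/LVDs, never drawn separately.
  To give the derived FS a realistic distribution, the LVDd/LVDs noise
  (measurement and examiner components) is correlated at 0.85; this
  yields an FS 5th percentile near 23–24% and an FS R² on body weight of
  ~0.03–0.04, matching the behaviour of real FS data. The truth object's
  `fs_*` fields describe this implied marginal law (slope −0.065) for
  documentation; they are not a second generative path.
* **Deviant breeds** — multiplicative offsets on the original scale:
  Saluki chambers ×1.15/1.18, Afghan ×1.08/1.10, Whippet ×1.08/1.12,
  Newfoundland ×0.90 on all six, Irish Wolfhound walls ×0.92 and chambers
  ×0.95. These were set once by inverting the normal tail mass to land
  near the exceedance pattern reported for those breeds (Saluki ~30%
  above for chambers, Newfoundland ~14–19% below, Irish Wolfhound ~7–8%
  below) and are scale multipliers, not exponent changes — exponent
  deviations are not identifiable from published deviance tables.
* **Gross outliers** — with probability 0.001 a measurement is multiplied
  or divided by 10, emulating transcription errors; these are what the
  fence screen exists to remove.

What the generator does *not* emulate: disease states, view-dependent
measurement differences, drift over calendar time, repeated screening of
the same dog, missing-data patterns of real registries (missingness only
arises from screening and invalid FS), or heavier-tailed measurement
error. Passing tests therefore demonstrate the correctness and
calibration of the estimators under the stated model, not robustness to
every artefact of real registry data.

## Experiment sizes and seeds

Parameter-recovery and coverage experiments use 20,000-dog cohorts
restricted to the breeds whose deviance multiplier is 1.0 (breed mix
rescaled proportionally): recovery of a generative parameter is only
meaningful on data generated from that parameter, and the default cohort
deliberately contains deviant breeds whose presence biases the population
fit (by about +0.04 on a — a property of the study design the package
reproduces, not an estimator defect). Coverage is measured out of sample:
fit on a random half, count exceedances on the other half. All
experiments are seeded; the same seed reproduces every table bit-for-bit.

## Known limitations

* The exact PI assumes independent lognormal errors; examiner clustering
  makes it very slightly anticonservative (empirical coverage ~94.6–95.2%
  at the 95% level in the tests).
* Fences with k = 3 assume roughly symmetric log-scale distributions;
  strata smaller than ~20 dogs give noisy quartiles (they are pooled, but
  the pooled stratum mixes breeds of different sizes — screening there is
  conservative for location outliers).
* The GCV grid is fixed; pathological smoothing problems could prefer λ
  outside 10⁻⁴…10⁶.
* The group-comparison additive model shares one smooth between groups;
  a group-specific smooth difference is out of scope.
* Breed-specific reference intervals (rather than deviance flags) are
  deliberately not fitted.
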