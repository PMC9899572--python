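# Methods

This note documents the models and procedures `carbquality` implements,
the parameters that matter, the design choices made where convention does
not fully pin down the computation, and what the synthetic-data studies do
and do not demonstrate.

## 1. From FFQ responses to diet profiles

An FFQ response assigns each catalogue item one of nine ordered frequency
categories. These are mapped to servings/day by the midpoint convention
standard for Willett-style questionnaires:

| category | servings/day |
|---|---|
| never | 0 |
| 1–3/month | 2/30 |
| 1/week | 1/7 |
| 2–4/week | 3/7 |
| 5–6/week | 5.5/7 |
| 1/day | 1 |
| 2–3/day | 2.5 |
| 4–6/day | 5 |
| ≥6/day | 6 |

The table is a single module-level constant so an alternative convention
is a one-line change. Daily intake of every nutrient is the sum over items
of servings/day × per-portion amount. Items without a response are imputed
as "never" (the count is logged); energy comes from the catalogue's kcal
field rather than being recomputed from macronutrients, avoiding
Atwater-rounding drift.

The dietary glycaemic index is the carbohydrate-weighted mean of item GIs
(glucose = 100). Items with a missing GI contribute to carbohydrate totals
but not to the weighted mean, which keeps the dietary GI defined for diets
containing minor untabulated items; a diet with no GI-bearing carbohydrate
has an *undefined* GI (`None`/NaN), never zero. Whether GI-missing items
should instead receive a default GI is not settled in the field; exclusion
from the mean is the default here and the alternative is a caller-side
catalogue edit.

Liquid-carbohydrate classification (juices, sugar-sweetened and cola
beverages, beer, milk drinks) is an item-level catalogue flag, not a
hard-coded food list, as is grain/whole-grain membership.

## 2. Carbohydrate Quality Index

Components per profile:

* dietary GI (inverted at scoring time),
* whole-grain carbohydrate / total-grain carbohydrate,
* fibre intake in absolute g/d (not energy-adjusted),
* solid carbohydrate / total carbohydrate.

A grain-free diet has an undefined whole-grain ratio; it is scored 0
(worst) and flagged, which affects only grain-free diets.

**Quintile scoring.** Cut points are the empirical 20/40/60/80th
percentiles computed with the linear-interpolation ("type 7") estimator,
fixed so cutoffs are reproducible bit for bit. A value equal to an
interior cut point falls in the *lower* quintile; the same boundary rule
is used for tertiles in the component analyses. Scores run 1–5 (GI: 5–1),
the total runs 4–20, and categories are 4–9 / 10–14 / 15–20. Missing
component values propagate as missing scores — never silently as the
lowest quintile.

Cutoffs are derived once from the baseline analysis population and reused
for 10-year profiles, keeping the score comparable over time; per-wave
re-derivation is available behind a flag (`reuse_baseline_cutoffs=False`)
since either choice is defensible. By default the reference population for
quintiles is the analysis sample itself; callers holding a larger source
population can pass externally derived cutoffs (they serialise to a small
CSV).

**Carbohydrate quantity** uses 4 kcal/g (Atwater) for carbohydrate energy
against total energy (which includes alcohol): bands ≤40 %, >40–<50 %,
≥50 %, with both printed boundaries inclusive as written.

**Modified Mediterranean score.** Seven of the classic nine median-based
items (cereals removed to avoid overlap with the CQI; alcohol removed
because it is adjusted for separately). One point per beneficial item
(vegetables, legumes, fruit & nuts, fish, MUFA:SFA ratio) at/above the
population median and per detrimental item (meat, dairy) below it. With
SFA = 0 the MUFA:SFA ratio is undefined; the point is granted iff any MUFA
is consumed. Categories 0–2 / 3–4 / 5–7 — an even split of the 0–7 range,
since no standard cut points exist for the 7-item variant.

## 3. Cohort assembly

The exclusion cascade runs in a fixed order: (1) < 33 months in the cohort
("2 years and 9 months"), (2) men, (3) lost to follow-up, (4) no pregnancy
during follow-up, (5) GDM before baseline, (6) prevalent diabetes or
antidiabetic/insulin treatment, (7) energy intake outside the 1st–99th
percentile. The energy percentiles are computed on the sample remaining at
that step (the cascade position matters and is therefore fixed, not
recomputed on the full roster). The report records (step, n excluded,
n remaining) and renders as CSV or a text flow chart.

Each woman contributes one analysis row per pregnancy, censored after her
first GDM-positive pregnancy (that pregnancy is retained; later ones are
dropped). Exposure is the baseline profile, replaced by the 10-year
profile for pregnancies at > 10 years of follow-up when that questionnaire
exists; when it does not, baseline is carried forward and the row is
flagged (`baseline_fallback`). All other covariates are frozen at
baseline — only diet is wave-updated. Dates are fractional years since
enrolment; there is no calendar arithmetic. Physical activity is
Σ hours/week × MET over reported activities.

## 4. Estimation

All models are logistic GEE (binomial family, logit link) with pregnancies
clustered within women, an exchangeable working correlation by default,
and the cluster-robust sandwich variance; 95 % CIs use the normal
multiplier 1.96. The solver runs to a relative coefficient change of 1e-8
(max 100 iterations); non-convergence raises a warning and is flagged on
the fit. Estimation is by `statsmodels.GEE`; this package owns the model
specifications, exposure codings and table layouts.

Adjustment sets are nested: model 1 (age at first cohort pregnancy, BMI);
model 2 adds parity, family history of diabetes, physical-activity
tertiles, television hours, smoking status, total energy, Mediterranean
category, fast-food category, snacking, special diet; model 3 adds alcohol
category, CVD and hypertension. "Model 4" is context-dependent: for the
category analysis it is model 3 *minus* the Mediterranean covariate; for
the component-tertile analysis it is model 3 *plus* the other three
(continuous) components. Missing covariate values are handled
complete-case per model, and each fit reports its own n.

* **Trend test**: the category indicators are replaced by the analysis
  sample's median CQI total within each category, entered as one
  continuous term; the slope's robust p-value is the trend p.
* **Per-increment OR**: the CQI total divided by the increment (default 2
  points) as a single continuous term.
* **Joint analysis**: a 9-level cell factor (CQI category × quantity
  band), reference = lowest quality & lowest quantity. Empty non-reference
  cells are reported and dropped with a warning. The interaction p-value
  comes, by default, from a single product term of the two ordinal codes
  (0/1/2 each, 1 df); a 4-df joint Wald test over the full product
  contrasts is available via `interaction="joint"`. Neither
  parameterisation is canonical; both are provided.
* **Sensitivity runner**: named scenarios (nulliparous / parous
  restriction, first-pregnancy-only, age-at-entry and/or age-at-pregnancy
  adjustment swaps) refit the main model and tabulate side by side.

Categorical covariates enter as indicator contrasts with the first level
as reference; continuous covariates untransformed. Separation (an
exposure level with zero events) triggers a warning naming the variable.

## 5. Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
nutritional reality (catalogue compositions are synthetic, and absolute
intake levels run high relative to typical cohorts; only the relative
structure is calibrated).

**Latent-trait diet model.** Each woman has a latent diet-quality trait
q ~ N(0,1) and four component-specific latents loading on it. Responses
shift with the latents: whole-grain, fibre-dense, solid-carbohydrate items
up with quality; refined-grain, liquid-carbohydrate and high-GI items
down. The GI preference acts only as a *penalty* on high-GI items — a
symmetric low-GI boost would drag fibre-rich low-GI vegetables and
legumes along with it and overcouple the components. Loadings are
calibrated once so the realised fibre × whole-grain intake correlation at
default settings is ≈ 0.263 (a deliberately modest value: the two
components are meant to measure different things, and part of the
correlation is structural because whole-grain items carry fibre of their
own). The 10-year wave drifts the latents (AR-style, 0.8 persistence).

**Outcome model.** GDM per pregnancy follows a logistic model with a
woman-level normal random intercept (default SD 0.5 on the logit scale)
inducing within-woman correlation. Configured odds ratios are
**population-averaged**: the conditional intercept and effects are
calibrated by Gauss–Hermite marginalisation so that E_b[expit(η_c + b)] =
expit(η_m) holds per observation. Without this step, seeded conditional
ORs would differ from what a marginal estimator (GEE) consistently
targets, and recovery studies would be biased by the attenuation factor
rather than testing the estimator. Defaults: 3 % baseline (reference
category) incidence; category ORs (1.0, 0.85, 0.67); optional linear
(per-2-point) and 3×3 joint-cell effect modes; modest covariate effects
(age, BMI, family history, current smoking) confounded with diet quality
in the usual directions (lower-quality women younger, less active, more
often current smokers, lower energy intake).

**Cohort structure.** 1–3 pregnancies per woman with probabilities
(0.40, 0.41, 0.19), mean ≈ 1.79 pregnancies/woman; pregnancy times uniform
over 0.5–11.8 years so ~15 % fall after year 10 and exercise the exposure
update. Roster strata triggering every exclusion step are included at
small configurable fractions. Regeneration from (config, seed) is
bit-identical, and the ground truth is serialised beside the data.

A fast generation path (`simulate_analysis_dataset`) draws the
pregnancy-level analysis table directly — component values from the latent
model, scored through the real quintile code, outcomes from the calibrated
model — and is used for replicated estimation studies where the FFQ layer
would only add runtime.

**What passing tests show.** Recovery and calibration results demonstrate
that the estimation machinery is consistent and its robust intervals are
honest *under the generator's assumptions* (logit-linear marginal model,
normal random intercept, exchangeable-by-construction within-woman
dependence, missingness-free data). They cannot certify behaviour under
real-data features the generator omits: differential FFQ measurement
error, informative loss to follow-up, secular diet trends beyond the
simple 10-year drift, or outcome misclassification.

## 6. Simulation-study sizes and numerical choices

* Coverage study: 200 replicated cohorts of 20 000 women; the robust 95 %
  CI for the seeded high-vs-low category OR (0.67) must cover it in
  ≥ 93 % of replicates. Replicated fits use the independence working
  correlation: with a cluster-robust sandwich the CI is valid under any
  working correlation, and the independence estimator's mild efficiency
  loss makes the check conservative. The exchangeable fits are exercised
  by the single-fit tests and by an invariant test confirming
  exchangeable ≡ independence (to ~1e-2, the finite-sample noise of the
  estimated correlation) when no within-woman correlation is seeded.
* Joint-cell recovery: 12 cohorts of 30 000 women, geometric-mean estimate
  of the seeded 0.30 cell OR within 10 % relative error.
* Type-I error: 500 null cohorts of 3 000 women; trend-test and
  interaction-test rejection at α = 0.05 within 5 % ± 2 pp. Pilot z-statistic
  SDs are ≈ 1.00–1.01 at this size, i.e. the sandwich is essentially
  calibrated and the band mainly absorbs binomial noise.
* Gauss–Hermite marginalisation uses 64 probabilists' nodes and a
  200-point monotone grid with linear interpolation; the quadrature error
  is ~1e-6 on the probability scale, far below all tolerances.
* All randomness flows from `numpy.random.default_rng(seed)`; every test
  and script seed is fixed.

## 7. Known limitations

* Quintile/tertile boundary handling ("equal goes lower") is one of
  several defensible conventions; results for heavily tied components can
  shift under the alternative.
* The 1-df ordinal interaction test trades power for parsimony; the 4-df
  variant answers a slightly different question. Neither is privileged.
* Logistic ORs are non-collapsible: adding a covariate that is associated
  with the outcome changes the marginal exposure OR even without
  confounding. The "orthogonal covariate leaves the OR unchanged"
  invariant is therefore tested with a null-effect covariate, where
  collapsibility holds.
* The energy-plausibility filter always trims ~2 % of any continuous
  energy distribution; "no filter applies" is only achievable with ties at
  the percentile boundaries.
* GEE assumes non-informative cluster sizes; the generator draws pregnancy
  counts independently of the random intercept, so this holds by
  construction in the tests but is an assumption on real data.
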