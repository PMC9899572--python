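# carbquality

Carbohydrate-quality epidemiology in pre-conceptional cohorts: from food
frequency questionnaires (FFQ) to repeated-measures odds ratios for
gestational diabetes mellitus (GDM).

## What this package is for

Nutritional-epidemiology cohorts such as the *Seguimiento Universidad de
Navarra* (SUN) project assess diet with a semi-quantitative FFQ (136 food
items, nine frequency options each) at baseline and again after 10 years,
and follow women through their pregnancies. A question of current interest
is whether the **quality** of the carbohydrates a woman eats before
conception — not just their amount — is associated with her risk of
developing gestational diabetes.

`carbquality` implements that analysis end to end for researchers working
with FFQ-based cohort data:

1. **`ffq_engine`** — converts item-level frequency responses into daily
   diet profiles: each nutrient is Σ (servings/day × per-portion amount),
   and the dietary glycaemic index is the carbohydrate-weighted mean
   GI = Σᵢ carbᵢ·GIᵢ / Σᵢ carbᵢ over GI-bearing items (glucose = 100).
2. **`cqi_scoring`** — the four-component **Carbohydrate Quality Index**:

   | component | direction |
   |---|---|
   | dietary glycaemic index | scored 5 → 1 (inverted) |
   | whole-grain / total-grain carbohydrate ratio | scored 1 → 5 |
   | dietary fibre intake (g/d) | scored 1 → 5 |
   | solid / total carbohydrate ratio | scored 1 → 5 |

   Each component is scored by quintiles of the reference population; the
   total CQI ranges 4–20 and is categorised 4–9 / 10–14 / 15–20. The module
   also provides the carbohydrate-quantity bands (≤40 %, >40–<50 %, ≥50 %
   of energy from carbohydrate) and a 7-item modified Mediterranean-diet
   score (the classic 9-item median-based score minus the cereals and
   alcohol items).
3. **`cohort_pipeline`** — the analysis-population machinery: a
   seven-step exclusion cascade (insufficient time in cohort, men, lost to
   follow-up, no pregnancy, prior GDM, prevalent diabetes, implausible
   energy intake outside the 1st–99th percentile), censoring of all
   pregnancies after a woman's first GDM event, and exposure updating (the
   10-year FFQ replaces baseline for pregnancies more than 10 years after
   enrolment).
4. **`estimation`** — repeated-measures logistic models fitted by
   generalised estimating equations (binomial family, logit link,
   exchangeable working correlation, cluster-robust sandwich variance),
   with pregnancies clustered within women: category ORs under nested
   adjustment sets, the median-based linear-trend test, per-2-point ORs,
   per-component tertile models, the 3×3 joint quality × quantity analysis
   with interaction test, and a sensitivity-scenario runner.
5. **`synthetic_data`** — a seeded generator for catalogues, responses and
   multi-pregnancy cohorts with known ground truth (configurable odds
   ratios, ~3 % baseline GDM incidence, woman-level random intercept,
   Table-1-style confounding), so the whole pipeline is testable without
   access to any cohort's raw data.

## Worked example

```python
import numpy as np
import carbquality as cq

cfg = cq.SimulationConfig(n_women=4000)           # seeded OR: high vs low CQI = 0.67
cohort = cq.generate_cohort(cfg, seed=1)

eligible, report = cq.apply_exclusions(cohort.roster, cohort.pregnancies)
print(report.to_text())

items = cq.catalogue_from_frame(cohort.catalogue)
base = cq.compute_diet_profiles(
    cohort.responses[cohort.responses.wave == "baseline"], items)
ten = cq.compute_diet_profiles(
    cohort.responses[cohort.responses.wave == "10-year"], items)
data, summary = cq.build_analysis_dataset(
    eligible, cohort.pregnancies, baseline_profiles=base, ten_year_profiles=ten)
print(summary)

fit = cq.fit_gee(data, cq.ModelSpec(exposure="cqi_category", adjustment="model1"))
print(cq.format_or_table(fit))
```

Output (seed 1):

```
Participants in roster: n = 4000
  |-- excluded: in cohort < 2 years 9 months (n = 68)
  v   remaining: n = 3932
  |-- excluded: men (n = 155)
  v   remaining: n = 3777
  |-- excluded: lost to follow-up (n = 196)
  v   remaining: n = 3581
  |-- excluded: no pregnancy during follow-up (n = 364)
  v   remaining: n = 3217
  |-- excluded: GDM prior to baseline (n = 11)
  v   remaining: n = 3206
  |-- excluded: prevalent diabetes or antidiabetic treatment (n = 11)
  v   remaining: n = 3195
  |-- excluded: implausible energy intake (outside P1-P99) (n = 64)
  v   remaining: n = 3131
Final analysis sample: n = 3131
{'n_women': 3131, 'n_pregnancies': 5489, 'n_gdm': 155, 'crude_incidence_pct': 2.8238294771360906}
cqi_category (model1); n_obs=5489, n_women=3131
           low  1.00 (ref.)
           mid  0.67 (0.46, 0.98)
          high  0.51 (0.34, 0.78)
```

The crude incidence sits a little under the 3 % reference-category rate
because the seeded category effects are protective. The high-vs-low OR
estimate (0.51) carries the sampling noise of a single ~3 000-woman cohort
around the seeded population value of 0.67 — a robust 95 % CI at this
sample size spans roughly ±40 % of the point estimate; the replicated
recovery studies in `tests/test_acceptance.py` quantify this.

## Layout

```
src/carbquality/     ffq_engine, cqi_scoring, cohort_pipeline,
                     estimation, synthetic_data, cli
tests/               unit + property tests, test_acceptance.py
scripts/acceptance.py
docs/methods.md      models, parameters, design choices, limitations
```

A thin CLI exposes the generator: `carbquality simulate --seed 1
--n-women 4000 --out-dir cohort/`.
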