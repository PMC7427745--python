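# wearcon

Synthetic multi-sensor home monitoring of asthma control in children:
simulation, signal-level feature extraction, and multiply-imputed stepwise
logistic classification.

## Scientific problem

Whether a child's asthma is under control is usually judged in clinic from
symptom recall and a bronchoprovocation test. Wearable and home devices —
a single-lead ECG patch, a wrist actigraph, a handheld spirometer and
smart inhaler caps — record two weeks of daily life and could support that
judgement objectively. The analysis question is whether physiological
parameters extracted from those raw streams (respiratory-rate recovery
after exercise, lung-function variability, sleep timing, reliever use,
activity structure, …) can classify children as *uncontrolled* vs
*controlled*, against a clinical reference standard combining four
symptom-control items with an exercise bronchoprovocation test
(uncontrolled = ≥ 3 positive items or a post-exercise FEV1 fall > 12%).

Because real paediatric monitoring data cannot be shipped, the package
contains a calibrated simulator: each synthetic subject carries
ground-truth values of all ~28 home-monitoring parameters, drawn from
per-group distributions, and raw sensor streams are rendered from that
truth. The extraction chain then works only on the rendered raw data, so
the whole pipeline — signal processing, missing-data handling, model
selection — is exercised end to end and can be validated against the
known truth.

## What is implemented

* **Cohort simulator** (`wearcon.cohort`, `wearcon.config`): 89 subjects
  by default (27 uncontrolled, 32 controlled, 30 non-asthmatic controls),
  14 monitoring days; stylised single-lead ECG with respiratory amplitude
  modulation, 60-s actigraphy counts, tagged home-spirometry maneuvers
  with a configurable quality-control failure rate, and smart-inhaler
  event logs.
* **ECG features** (`wearcon.ecg`): Kaiser-window band-pass (0.45–39 Hz),
  derivative-energy QRS detection, ECG-derived respiration from the R−S
  amplitude, day/night heart-rate and respiratory-rate averages, and
  post-exercise recovery times (first sustained return of the 10-s moving
  median into a 5% band above baseline).
* **Actigraphy features** (`wearcon.actigraphy`): Evenson youth count
  cut-points, activity-bout statistics with a Weibull fit of bout
  durations, Cole–Kripke sleep/wake scoring with Webster rescoring, and
  nightly sleep metrics (total sleep time, wake-up time, efficiency,
  awakenings, restlessness).
* **Spirometry features** (`wearcon.spirometry`): ATS/ERS-style
  acceptability on summary indices, %-predicted values from swappable
  reference equations, baseline FEV1 variability, exercise-induced and
  symptom-related FEV1 changes.
* **Inhaler features** (`wearcon.inhaler`): actuation de-duplication,
  controller adherence, reliever totals and activity-linked reliever use.
* **Missing data** (`wearcon.imputation`): monotone-pattern check;
  monotone sequential-regression imputation or multivariate-normal
  data-augmentation MCMC (m = 5 by default) with per-parameter bounds and
  log-scale columns; Rubin's rules pooling.
* **Classification** (`wearcon.model`): collinearity screen (|r| > 0.8),
  stepwise forward likelihood-ratio logistic selection (entry p < 0.10,
  removal p > 0.20) per imputed data set with majority voting and pooled
  refit, Firth-penalised fallback under separation, Nagelkerke R², odds
  ratios, and sensitivity/specificity/predictive values; plus routed
  univariate group comparisons (ANOVA/Tukey or Kruskal–Wallis/
  Games–Howell).

## Worked example

The whole study runs in one call (about two minutes on one CPU):

```python
from wearcon import CohortConfig, run_study
from wearcon.model import odds_ratios

result = run_study(CohortConfig(seed=1))
print(result.model.features)
print(round(result.model.nagelkerke, 3))
print(result.metrics.as_percent())
```

Output with seed 1:

```text
['wakeup_min', 'controller_adherence_pct', 'rr_recovery_s', 'reliever_after_activity']
0.936
{'sensitivity': 96.3, 'specificity': 100.0, 'ppv': 100.0, 'npv': 97.0}
```

Stepwise selection on this synthetic cohort lands on four parameters:
earlier waking, lower controller adherence, slower respiratory-rate
recovery after exercise and more post-exercise reliever use all raise the
predicted odds of uncontrolled asthma, in line with the univariate table
(`result.univariate`), where `rr_recovery_s` (p ≈ 3e-9), `wakeup_min`
(p ≈ 8e-10), `reliever_total` (p ≈ 7e-4) and the reliever placement
counts separate the groups most clearly.

A fixed four-covariate model (slopes 0.292 per %-point of FEV1
variation, 0.100 per reliever inhalation, 0.113 per second of
respiratory-rate recovery, −0.053 per minute of wake-up time) ships as
`wearcon.pipeline.published_model()`; its intercept is *synthetic* —
calibrated by maximum likelihood on the seed-1 cohort (13.047) — because
a slope-only model cannot be scored without one. Scoring that model on
the same cohort's extracted features gives:

```text
{'sensitivity': 88.9, 'specificity': 93.8, 'ppv': 92.3, 'npv': 90.9}
```

The same stages are scriptable: `wearcon simulate`, `extract`, `impute`,
`fit`, `score` and `report` (see `wearcon --help`) operate on CSV
bundles, so each stage can be inspected or replaced.

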