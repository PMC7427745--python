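# Methods

This note describes the simulation model, the feature-extraction chain,
the statistical pipeline, and the numerical choices. It documents what
the code computes; it makes no empirical claims beyond the package's own
outputs.

## 1. Study design being emulated

A two-week observational home-monitoring study of children (4–14 y) in
three groups — uncontrolled asthma, controlled asthma, non-asthmatic
controls (default sizes 27/32/30). Each subject wears an actigraph for
the full fortnight, an ECG patch for a two-day sub-window, performs
home spirometry around daily exercise and when symptomatic, and (if
asthmatic) uses smart-inhaler caps on a twice-daily controller and an
as-needed reliever. The clinical reference standard labels an asthmatic
child *uncontrolled* when ≥ 3 of 4 symptom-control items are positive
or the exercise bronchoprovocation FEV1 fall exceeds 12% (strictly).

## 2. Cohort simulation

### 2.1 Ground truth

Each home-monitoring parameter is drawn per subject from a per-group
distribution (`wearcon.config`):

* **Truncated normal** for approximately symmetric parameters
  (lung-function %-predicted, activity minutes, heart/respiratory
  rates, sleep durations), clipped to physiological bounds.
* **Lognormal matched to a median and IQR** for right-skewed positive
  parameters (recovery times, wake-up time, restlessness, reliever
  totals): μ = ln median, σ = (ln q3 − ln q1) / (2 × 0.6745).

Medication parameters are structurally undefined (NaN) for
non-asthmatic controls. Activity-linked reliever doses are allocated
from the total via per-group placement probabilities rather than drawn
separately, because their distributions are dominated by zeros.

The default locations and scales were chosen to emulate group contrasts
reported for clinically phenotyped paediatric cohorts (e.g. slower
respiratory-rate recovery, earlier waking and higher reliever use in
uncontrolled asthma). They are calibration settings of the simulator,
not estimates from data shipped with the package.

### 2.2 Schedules

Exercise: one bout per day, 6–30 min, between 15:00 and 17:30. Sleep:
nightly onset/wake times derived deterministically from the true total
sleep time, awake minutes and wake-up time — identical every night, so
extracted nightly averages equal the truth exactly (night-to-night
jitter would only blur the closed loop). Spirometry: 4–5 sessions
(pre + post pair) per fortnight, modelling partial compliance, plus a
symptom maneuver when the subject's plan includes a non-activity
reliever dose. Controller doses at 08:00 and 20:00 with ±10 min jitter;
the number taken is the adherence percentage rounded to whole doses.

### 2.3 Rendering raw streams

* **ECG** — rather than 43 M continuous samples, the renderer produces
  analysis segments inside a two-day window starting at noon of day 0:
  two 30-min daytime and two 30-min night resting segments plus the
  surroundings (−6 min / +16 min) of up to two exercise bouts. Beats
  are placed by inverting the trapezoid-integrated instantaneous heart
  rate on a 0.25-s grid; each QRS is a Gaussian R wavelet (σ = 10 ms)
  with a delayed negative S wavelet. R and S amplitudes are modulated
  sinusoidally at the instantaneous respiratory phase (20% depth),
  which is the ECG-derived-respiration ground truth. Optional additive
  Gaussian noise (15 µV) and sub-passband baseline wander. Exercise
  raises heart rate by up to 55 beats/min and respiratory rate by
  14 breaths/min with a sigmoidal ramp; the post-bout decay constant is
  τ = true recovery time / ln 20, so the analytic 5%-band crossing
  equals the true recovery time.
* **Actigraphy** — 60-s epochs over 14 days. Waking epochs receive
  axis-1 counts drawn from per-intensity ranges consistent with the
  Evenson cut-points; the daily minutes of light/moderate/vigorous
  activity match the subject's truth, sedentary filling the remainder
  of the waking day (the truth table's activity durations sum past
  24 h because real denominators are wear-time based). Sleep periods
  carry zero counts with quiet-wake awakenings (count 6) sized from
  the true awake minutes; count levels and two-epoch tapers are chosen
  so the Cole–Kripke scorer recovers onset and wake-up to ±1 epoch.
  A daily 20–40 min non-wear gap is inserted early afternoon.
* **Spirometry** — maneuvers are summary records (FEV1, FVC, PEF,
  FEF25–75, FET, back-extrapolated volume). Baseline FEV1 values are
  placed so that their mean and range reproduce the true mean
  %-predicted and variation; post-exercise and symptom maneuvers apply
  the true percentage changes. A configurable fraction (default 26.1%)
  of maneuvers is rendered to fail quality control (short expiration).
* **Inhaler log** — controller and reliever actuations as timestamped
  events; before/after-activity doses are placed 2–28 min around bout
  boundaries, other doses mid-morning, ≥ 90 s apart.

All rendering is deterministic given the configuration seed (per-subject
sub-streams via `default_rng([seed, subject, stream])`).

## 3. Feature extraction

Extraction consumes only the rendered raw streams.

* **ECG** (`wearcon.ecg`): zero-phase Kaiser FIR band-pass 0.45–39 Hz
  (60 dB ripple, 0.3 Hz transition, group-delay compensation);
  derivative-energy QRS detection (150 ms integration window, adaptive
  threshold at 0.2 × the 98th percentile, 200 ms refractory); R refined
  in ±50 ms, S as the minimum within 100 ms after R. ECG-derived
  respiration: cubic-spline interpolation of the R−S amplitudes to
  50 Hz; breaths = peaks with prominence ≥ 0.2 × IQR and ≥ 0.75 s
  spacing. Uniform 1-Hz rate series by interval inversion with
  plausibility masks (HR 30–250, RR 4–80). Daytime (08–20 h) and night
  (00–06 h) means require ≥ 50% usable samples; resting summaries
  exclude [bout − 1 min, bout + 10 min]. Recovery time: baseline =
  median of the 5 min before the bout; peak within ±60 s of bout end;
  recovery = first ≥ 10-s stay of the 10-s moving median within
  baseline + 5% of the excursion, searched 15 min, relative to bout
  end. Streams pass a ≥ 75% completeness gate.
* **Actigraphy** (`wearcon.actigraphy`): Evenson youth cut-points
  (100/2295/4011 counts/min, strict thresholds); bouts = maximal runs
  of moderate-or-above epochs, summarised by mean length and the
  maximum-likelihood Weibull scale (location fixed at 0, ≥ 10 bouts).
  Sleep: one-minute Cole–Kripke weights (0.001 × 106/54/58/76/230/74/67
  over t−4…t+2, sleep if < 1) with Webster rescoring rules a–c; the
  main sleep period runs from the first 5-epoch to the last 10-epoch
  sleep run inside each 18:00–12:00 night window. Intensity minutes are
  computed over waking worn epochs.
* **Spirometry** (`wearcon.spirometry`): acceptability on the available
  indices (BEV ≤ max(0.15 L, 5% FVC), FET ≥ 3 s, device PEF flag);
  %-predicted from linear-in-height per-sex reference equations
  (replaceable, e.g. by GLI, for real data); FEV1 variation = range of
  accepted baseline %-predicted values; exercise change pairs each bout
  with the last baseline ≤ 30 min before and the first post maneuver
  3–6 min after.
* **Inhaler** (`wearcon.inhaler`): actuations of one type < 60 s apart
  merge into one dose; adherence = doses/prescribed (uncapped);
  relievers within 30 min of a bout boundary count as before/after
  (nearer boundary wins, tie → before).

The extractors are validated closed-loop: with distribution scales set
to zero and rendering noise off, extracted features match the profile's
truth exactly for event-based features and within stated tolerances for
signal-derived ones (see `tests/`). Two deliberate exceptions: the mean
bout length and Weibull scale truths are expressed in sub-minute units
that a 60-s-epoch analysis cannot recover, so these two parameters are
carried as group-calibrated draws, not closed-loop targets.

## 4. Statistical pipeline

1. **Labels**: each asthmatic subject receives a clinical assessment
   consistent with its group (uncontrolled subjects meet the symptom
   clause, the provocation clause, or both, in clinically plausible
   proportions) and is labelled through the same ≥ 3-items / > 12% rule
   used for real data.
2. **Missingness**: 11.5% of the asthmatic feature cells are masked
   completely at random (structurally undefined cells excluded).
3. **Multiple imputation** (`wearcon.imputation`): if the pattern is
   monotone, sequential regression along the monotone column order with
   posterior draws of the coefficients and residual variance; otherwise
   multivariate-normal data augmentation (Jeffreys prior, inverse-
   Wishart posterior draw of Σ, 200-iteration burn-in, thinning 10)
   producing m = 5 completed sets. Right-skewed columns (recovery
   times, wake-up, restlessness) are imputed on the log scale; imputed
   values respect per-parameter bounds (redraw, then truncate);
   observed cells are never altered.
4. **Selection and fit** (`wearcon.model`): per completed set, a
   pairwise collinearity screen (|r| > 0.8 bars joint entry), then
   stepwise forward selection by likelihood-ratio test (entry p < 0.10)
   with backward removal (p > 0.20). All likelihood-ratio tests use
   unpenalised log-likelihoods; when the MLE is unstable
   (non-convergence or quasi-separation) coefficients come from a
   Firth-penalised fit but the comparison likelihood is still the plain
   likelihood at those coefficients, keeping p-values comparable across
   models. Features selected in a majority of the m sets are refitted
   per set and pooled with Rubin's rules (T = Ū + (1 + 1/m)B, t-based
   intervals with Rubin degrees of freedom). Fit is summarised by the
   mean Nagelkerke R² and odds ratios; subjects are classified by the
   mean predicted probability across imputations (> 0.5).
5. **Univariate reporting**: per parameter, Shapiro–Wilk and Levene
   tests route to one-way ANOVA + Tukey HSD or Kruskal–Wallis +
   Games–Howell.

## 5. Numerical and implementation choices

* Time is seconds since local midnight of monitoring day 0; CSV output
  anchors ISO timestamps at a nominal Monday (2024-01-08).
* Sensor bundles persist as plain CSV (one directory per subject).
* The FIR filter length follows the Kaiser design formula for 60 dB at
  a 0.3 Hz transition (≈ several thousand taps at 250 Hz); filtering
  uses FFT convolution with integer group-delay compensation.
* The inverse-Wishart draw uses df = max(n − 1, p + 1) with a 1e-6
  ridge on the scatter matrix for numerical stability.
* The Firth fit is an IRLS with hat-value score correction; its
  reported covariance is the inverse penalised information.
* Default m = 5, burn-in 200 and thinning 10 keep the full study inside
  a two-minute single-CPU budget; all stages are deterministic given
  the configuration seed.

## 6. Scope and limitations

* The simulator is stylised: ECG morphology is a two-wavelet QRS (no P
  or T waves, no arrhythmia, no electrode artefact); actigraphy counts
  are drawn from flat per-intensity ranges; spirometry curves are
  summary records only, so flow–volume shape criteria cannot be
  checked.
* The nightly schedule is identical across nights by design; variance
  components of sleep metrics are therefore not realistic.
* Group distributions are independent across parameters within a
  subject apart from the structural links built into rendering;
  real physiological correlations (e.g. HR–activity coupling beyond
  exercise bouts) are not modelled.
* Classification metrics are in-sample, as in the emulated design; no
  cross-validation or external validation set is provided.
* The fixed four-covariate model ships without a published intercept;
  the default intercept is calibrated on a synthetic cohort and is
  clearly marked as such.
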