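# Methods

`nighteda` analyses nocturnal wrist-wearable recordings for episodic
headache research.  This note documents the models and procedures the
package implements, the choices made where the design was genuinely
open, and what the synthetic-data experiments do and do not establish.

## 1. Signal model and EDA processing

Skin conductance (EDA, µS, 4 Hz) is modelled as

```
EDA(t) = tonic(t) + phasic(t) + ε(t)
```

where `tonic` is the slow thermoregulatory baseline, `phasic` the
superposition of skin-conductance responses (SCRs), and `ε` measurement
noise.

**Cleaning** applies, in a fixed order: (1) exclusion of out-of-bed
minutes (actigraphy-derived state channel); (2) masking of slope
artifacts, |dEDA/dt| > 5 µS/s, padded by 2 s; (3) removal of range
outliers outside [0.01, 60] µS; (4) linear interpolation of invalid
runs ≤ 5 s with valid neighbours on both sides; (5) removal of residual
valid segments < 30 s; (6) decomposition.  A night retaining < 30 min
of valid in-bed signal is flagged unusable.  The slope and range
thresholds are conventional wearable-EDA QC values and are
configurable; they are not estimated from data.

**Decomposition.** Tonic is a centered moving median over an 8-s window
(33 samples at 4 Hz), edge-truncated, computed independently per valid
segment; phasic is the residual, so additivity holds exactly at every
valid sample.  A moving median passes slow drift into tonic and leaves
fast excursions in phasic; the window must sit between the SCR time
scale (seconds) and the drift time scale (minutes).  Note that the
median partially absorbs the SCR itself: a kernel with 1-s rise and 3-s
decay retains ≈ 69% of its amplitude in the phasic component (computed
directly), so the effective detection floor in *true* amplitude is
≈ 0.0073 µS for the 0.005 µS phasic threshold.

**SCR peaks** are strict local maxima of phasic within a valid segment,
paired with the most recent local minimum of the same segment
(trough-to-peak rule).  Peaks with amplitude < 0.005 µS are rejected;
among surviving peaks closer than 1 s, the larger amplitude wins (ties
to the earlier peak) — implemented greedily in priority order, which
equals the recursive dominance fixed point of the rule.  The 0.005 µS /
1 s defaults are deliberately conservative sensitivity-analysis
settings; both are configurable.

**EDA storms.** Each maximal in-bed interval is tiled with consecutive
half-open 30-s epochs anchored at the interval start (trailing epoch
truncated).  An epoch is positive when it contains ≥ 3 accepted peak
times; positive epochs separated by ≤ 5 min (gap measured end-of-one to
start-of-next) merge into one storm.  Storms never bridge separate
in-bed intervals, so no storm overlaps an out-of-bed minute.  Nightly
summaries report the median cleaned ("total") EDA, peak rate and storm
rate per *valid in-bed hour*, and both the mean and the total storm
duration; downstream correlation analyses use the mean by default.

## 2. Night QC, blocks and features

A night is *usable* when missing in-bed minutes are strictly < 30% of
expected in-bed minutes and a diary entry exists for the morning the
night ends on.  A night is keyed to that morning's calendar date, so
"next-day headache" is the diary value of the same date.

Usable nights are tiled into non-overlapping 5-min blocks from the
start of each maximal in-bed run; trailing partial runs are dropped to
keep block statistics comparable.  Each block carries 4 statistics
(median, min, max, sample SD) of 9 channels: cleaned total EDA (valid
samples only), skin temperature, pulse rate, PRV, respiratory rate, and
four per-minute 0/1 time-in-state indicators (in bed, asleep, awake in
bed, out of bed).  The indicator convention means the block *sums* are
the minutes-per-state counts; a nightly-constant alternative was
considered and rejected because it carries no within-night information.
Blocks with any undefined statistic are dropped so the model matrix has
no missing values.  A separate block table for group statistics
averages the 1-min aggregate channels over 5-min windows, dropping
blocks with > 2 of 5 minutes missing (majority-present rule).

## 3. Personalized prediction

One model per participant maps block features to the night's next-day
headache label.  All blocks of a night move together through every
split ("night-level splitting").

* **Outer loop**: leave-one-night-out (LONO).  The held-out night's
  block probabilities are averaged into one nightly score.
* **Inner loop**: within each outer training set, every (headache
  night, headache-free night) pair is enumerated; for each
  hyperparameter grid point the model is fit on the remaining nights
  and scored on the held-out pair's blocks by block-level average
  precision (a 1-vs-1 *nightly* PR curve is degenerate, so the inner
  criterion stays at block level).  The grid point with the best mean
  inner AUPRC wins; ties go to the simpler point (stronger elastic-net
  penalty; shallower/smaller trees), then grid order.  With no feasible
  pair, tuning is skipped and the grid midpoint used.
* **Weights and scaling**: inverse-frequency class weights at night
  frequency, `w_c = N/(2 N_c)`, applied to every block of class `c`;
  centering/scaling statistics are computed from training blocks only
  and frozen into the fitted pipeline.
* **Learners**: elastic-net logistic regression (saga), random forest,
  and histogram gradient boosting.  Exhaustive pair enumeration times
  the full grids is computationally heavy (the number of inner fits is
  `O(nights² · grid)`), so `ModelConfig.max_inner_pairs` can evaluate a
  seeded subset of the enumerated pairs; the enumeration itself is
  always complete.  The validation suite uses capped pairs and compact
  grids (sizes in §6).

**Evaluation** is at the nightly-score level: AUROC by the midrank
(pairwise) rule with half credit for ties; AUPRC as step-wise average
precision; prevalence; operating points at probability thresholds 0.25
/ 0.50 / 0.75 with "predict positive iff score ≥ threshold".  A model
is called *clinically informative* when AUROC ≥ 0.70 and AUPRC ≥
prevalence + 0.10.  A participant whose nights all share one label
raises `SingleClassError` — the model cannot be computed, matching the
all-headache participant case.  `rates_to_metrics` converts
(prevalence, sensitivity, specificity) into precision and accuracy via
the standard identities; it is used to check printed threshold tables
for internal consistency.

## 4. Group statistics

**Nightly contrasts.** For each nightly wearable measure,
`value ~ headache + (1 | participant)` is fit by REML (Powell
optimization; the default gradient method can stall near the variance
boundary).  The fixed-effect contrast is tested with Satterthwaite
denominator degrees of freedom computed from the expected REML
information of the variance components
(`df = 2·Var(c'β)² / (∇Var' I⁻¹ ∇Var)`); the implementation matches
lme4/lmerTest to ~4 decimals on shared data.  Features with sample
skewness > 1 are log(1+x)-transformed (configurable override) and
estimates are reported on the transformed scale.  The standardized
effect is Hedges' g with the total-variance denominator,
`g = J(df) · est / √(σ²_intercept + σ²_residual)`,
`J(df) = 1 − 3/(4df − 1)` — the mixed-model analogue of a pooled SD.

**PROM correlations.** Nightly measures are averaged over usable
nights per participant and correlated with WPI, SSS, FM score
(= WPI + SSS, range 0–31), MIDAS, and PROMIS fatigue/sleep-disturbance
T-scores by Spearman's ρ (midrank ties).  Two-sided p-values are exact
permutation enumerations for n ≤ 8 and the t approximation otherwise,
reported without multiplicity correction (an optional Bonferroni flag
exists but is off by default, matching the exploratory framing).
Missing PROMs are dropped pairwise; correlations need ≥ 3 complete
pairs.

## 5. The synthetic cohort generator

The generator produces participant-nights with known ground truth so
every stage is testable without raw device exports.

* **In-bed duration**: Normal(8.5 h, 1.8 h), redrawn below 3 h.
* **Nightly arousal**: a latent mean-one lognormal multiplier
  (log-SD 1.0) representing the night's sympathetic tone.
* **SCR events**: two-state Poisson train — background 12 events/h and
  `Poisson(2 · arousal · e^{0.4·trait})` storm windows per night
  (uniform 2–8 min long, non-overlapping) with 10 extra events/min
  inside windows; both rates scale with arousal.  A 1.5-s refractory
  thins events (sudomotor refractoriness; closer events are physically
  unresolvable by trough-to-peak detection).  Amplitudes are lognormal
  with median 0.05 µS (log-SD 0.7).
* **Waveform**: tonic = participant baseline (uniform 0.3–2.0 µS)
  × arousal^0.5 × lognormal nightly jitter (log-SD 0.15) + a smooth
  random walk (0.10 µS/√h); SCR kernels rise linearly over 1 s and
  decay exponentially (τ = 3 s); noise is AR(1) Gaussian (φ = 0.99,
  marginal SD 0.003 µS) — conductance sensors are band-limited, and
  white noise at 4 Hz would bury the 0.005 µS amplitude floor.
* **Vitals**: pulse rate, PRV, respiratory rate and skin temperature
  are participant-level set-points with small nightly jitter plus
  stationary AR(1) within-night variation; they carry no injected
  headache signal.
* **Corruption**: Poisson dropouts (1/h, 5–60 s), spike artifacts
  (2/h), out-of-bed excursions (1 per night, 2–10 min, +0.5 µS motion
  offset so a failure to exclude them is detectable), whole-night
  missingness (8%).
* **Labels**: `P(headache) = logistic(β₀ + β_storm · z)` with `z` the
  within-participant z-score of the realized nightly storm rate
  (per in-bed hour); β₀ = −0.32 targets ≈ 42% prevalence and
  β_storm = 1.0 a moderate link by default.
* **PROMs**: the FM score is linked to the participant's realized mean
  storm rate through a Gaussian copula calibrated so the *population*
  Spearman correlation equals `prom_link_rho` (default 0.7), then
  mapped monotonically to the 0–31 integer scale (median ≈ 11) and
  split into WPI + SSS respecting their ranges; MIDAS is lognormal
  with 20% missingness.

The arousal coupling is a deliberate modelling commitment: storm-prone
nights show elevated background phasic activity *and* a raised
baseline throughout the night.  Without it, a handful of storm minutes
out of ~500 in-bed minutes would leave the 5-min block features with
essentially no per-block signal, and no block-level learner could
recover the nightly effect even in principle.

**What the generator does not emulate**: sleep architecture and stage
transitions, menstrual-cycle or medication effects, circadian tonic
trends, signal-carrying cardiovascular channels, device-specific
artifact morphology.  Tests passing on this generator therefore show
the *pipeline machinery* is correct and leakage-free and that effects
of the assumed form are recoverable — not that real nocturnal data
carry such effects.

## 6. Validation experiments and problem sizes

The test suite and `scripts/acceptance.py` rerun the methods at sizes
chosen to exercise each property while keeping a full run within
minutes on one CPU:

* storm-detector oracle equivalence: 1,000 random peak configurations
  over ≤ 12-h spans (300 in the script);
* SCR recovery: 50 corrupted nights at default noise, F1 pooled over
  nights with ±2-s matching (observed ≈ 0.97); exact-count check on 10
  noiseless nights with fixed 0.05 µS amplitudes and no storms — the
  fixed amplitude keeps every event above the decomposition-attenuated
  floor, so exactness is a property of the detector rather than of the
  amplitude tail;
* CV leakage null: 20 night-label permutations of a 40-night
  participant, elastic net, singleton grid — mean LONO AUROC must stay
  in [0.40, 0.60];
* signal recovery: β_storm = 1.5, ~40 nights, best of the three
  learners (singleton grids, seeded inner-pair cap) across 5 seeds;
* LMM calibration: 500 null cohorts (10 × 30 nights) for 95% CI
  coverage; 200 cohorts with an injected difference δ = 0.5 for bias;
* PROM-link recovery: 100 truth-only cohorts of 10 participants at
  target ρ = 0.7.

## 7. Known limitations

* **Recovery ceiling at small n.** With ~40 nights per participant and
  a Bernoulli label model, even the oracle that scores each night by
  its true generative storm rate has a LONO AUROC standard deviation of
  ≈ 0.07 across seeds; a fixed AUROC threshold is therefore met or
  missed partly by label-sampling luck, and block-level learners track
  the oracle from below.  Per-participant prediction at one-month scale
  is intrinsically seed- and participant-dependent — consistent with
  the wide per-participant performance spread such studies report.
* The moving-median decomposition attenuates SCR amplitudes ≈ 30%;
  reported mean amplitudes are phasic-scale, not true-kernel-scale.
* Satterthwaite df uses the expected (not observed) information;
  differences from lmerTest are ≲ 0.1% in df on tested data.
* The exact Spearman permutation p is feasible only for n ≤ 8; larger
  cohorts fall back to the t approximation.
* The CLI consumes the documented CSV dialects only; proprietary
  device exports must be converted upstream.
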