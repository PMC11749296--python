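# Methods

This note documents the models, the conventions where the problem left
genuine freedom, the numerical choices, and what the synthetic cohorts do
and do not establish about real data.

## Preprocessing conventions

CGM samples are snapped to a 5-min grid: each raw sample goes to its nearest
slot (ties toward the earlier slot), each slot keeps its nearest sample
(ties toward the earlier sample), and slots with no sample within ±150 s are
missing. Plausibility bounds of 20–500 mg/dL are enforced at read time and
duplicated timestamps are averaged.

Gap handling is deliberately asymmetric. Training segments may use
information from both sides of a gap, so interior gaps strictly shorter
than 30 min (a 30-min gap does not qualify) are filled by first-order
interpolation. Validation and test segments emulate deployment, so they are
filled only by a causal zero-order hold; samples before the first
observation remain missing. Per-sample provenance flags (`observed`,
`interpolated`, `zoh_filled`, `missing`) keep the two regimes auditable:
evaluation statistics use observed samples only, while forecasters run on
the filled series.

Subjects are split chronologically into contiguous 70/15/15
train/validation/test segments with boundaries at `floor(cumfrac * n)`.
Eligibility requires strictly more than 10 days of observed samples.

## The run-to-run rAR model

The central forecaster is a first-order autoregression through the origin,
ŷ(t+1|t) = a·y(t), with `a` re-estimated at every sample by exponentially
weighted recursive least squares. The forgetting factor μ ∈ (0,1) discounts
a sample τ steps old by μ^τ, giving an effective memory τ = 1/(1−μ); the
default μ = 0.675 weights essentially the three most recent samples, which
is what lets the model track post-prandial drops quickly at the price of
noise sensitivity (visible as the largest MAE among the families).

Numerical conventions:

* initialization a₀ = 1 (persistence — the safe cold start for glucose),
  P₀ = 10³ (diffuse), burn-in of 3 updates before any forecast is issued;
* the recursion is algebraically identical to the batch minimizer of
  Σ μ^(t−i)(y(i) − a·y(i−1))² + μ^t (a−a₀)²/P₀ — the test suite checks this
  identity to 1e-8 at every step, with the geometrically vanishing prior
  term included in the batch oracle;
* μ is fixed population-wise (an optional grid search on training one-step
  error is provided); a(t) and P(t) adapt online per subject — the only
  reading consistent with "adaptive" plus "one model per methodology";
* the state is re-initialized after a data gap of ≥ 30 min; ZOH-held samples
  inside shorter gaps do update the state, since a deployed system must keep
  adapting on held values;
* forecasts use raw mg/dL without detrending; multi-step forecasts iterate
  the one-step model, ŷ(t+k|t) = aᵏ y(t).

## ARIMA

The ARIMA(3,1,1) is identified by prediction-error minimization implemented
as summed conditional least squares: training traces are cut into contiguous
non-missing segments, each segment is differenced and conditioned on its own
first p values with zero initial innovations, and the pooled sum of squared
one-step errors is minimized with a Levenberg–Marquardt least-squares solver
started from a pooled AR OLS fit. No term couples two segments, so fitting a
gapped trace is exactly fitting its segments as independent realizations —
a property the tests verify, and which rules out off-the-shelf single-series
fitters as the implementation (one serves as a cross-check oracle on
single-segment data in the test suite). Invertibility is enforced by
reflecting an MA root inside the unit circle; a non-causal AR fit raises.
Forecasts rebuild the innovation sequence over a capped recent history
(48 samples) with the same conditional recursion and iterate the one-step
prediction with future innovations at zero.

## Windowed families

NN, LSTM, CNN-LSTM, RF and LGB are sequence-to-sequence regressors from a
12-sample (60-min) window — twice the output span, a common choice in CGM
forecasting — to all 6 future steps. Pairs are emitted only when window and
targets are contiguous non-missing samples of one subject. Inputs *and*
targets are standardized by the training-input mean/SD (both are glucose, so
one scale; standardizing targets conditions the network optimizers and makes
the constant-data behaviour exact). RF (100 trees, depth ≤ 15, ≥ 10 samples
per split) and LGB (200 trees, 31 leaves, learning rate 0.02) fit one
single-output model per step, deterministic under a fixed seed. The
feed-forward NN (hidden layers 32/16) is fitted with scikit-learn's
multilayer perceptron (ReLU, Adam, batch 32, ≤ 300 epochs, 30-iteration
patience). The LSTM (24/12) and CNN-LSTM (conv 16/8 with batch-norm and
max-pooling over LSTM 12/6, MSE loss, RMSprop at 1e-5) are defined against
the optional Keras backend and raise a clear error when it is absent; the
rest of the package is fully functional and tested without it.

## Alarms

An alarm is raised at origin t iff ŷ(t+PH|t) < AlarmLevel (strict), no alarm
was raised in the preceding PH minutes, and the concurrent reading is
≥ 54 mg/dL. The trigger tests the forecast at exactly PH — the tuner treats
PH as the operative horizon — with an any-step-up-to-PH variant available as
a flag. Suppression by a low current reading lifts as soon as the sensor
recovers to ≥ 54 mg/dL, so the strict reading also blocks an alarm issued at
the exact onset sample. Alarms issued while the current sample is ZOH-held
are allowed (real-time systems act on held values) and flagged `from_held`.

## Evaluation

Episodes are maximal runs below 54 mg/dL; runs separated by less than 15 min
of recovery merge (a merged episode may therefore contain ≥ 54 mg/dL samples
inside its span), and events shorter than 15 min are discarded — the
international CGM consensus minimum, consistent with the published median
episode duration of 25 [20–30] min. Both parameters are configurable.

Matching uses a 45-min window: an alarm at s is TP iff an onset lies in
(s, s+45] (onsets strictly after the alarm — an alarm during an ongoing
episode cannot claim it); an episode is detected iff an alarm lies in
[onset−45, onset), and its time gain is measured to the *earliest* such
alarm. Precision counts alarms, Recall counts events; the denominators
differ by design. FP/day divides by the calendar span of the evaluated
segment regardless of missingness. Time-gain quartiles are nearest-rank
(type 1), robust for the small per-segment event counts. MAE keeps the
absolute value inside the mean (a published variant typesets it outside the
summation, which would measure signed bias, not error). MAGE locates turning
points by sign-change scan after collapsing plateaus and averages the
absolute swings exceeding one (sample) SD of the trace.

## Tuning

The grid is PH ∈ {15, 20, 25, 30} min × AlarmLevel 35–80 mg/dL in 1-mg/dL
steps (selected thresholds in practice are integers). For every cell the
alarms are regenerated and the pooled metrics recomputed on
causally-filled validation data. F1 ties break toward lower FP/day (alarm
burden), then larger PH (more warning time), then lower AlarmLevel. Recall
is empirically weakly increasing in AlarmLevel on the instances tested, but
the shut-off can in principle suppress a later, better-placed alarm; the
property is observed, not asserted as a theorem.

## Synthetic cohorts

The generator emulates the statistical fingerprint of a PBH cohort rather
than insulin–glucose physiology: a mean-reverting basal process (default
SD 7 mg/dL, reversion half-life 2 h) around 100 mg/dL; four daytime meals
per day with half-cosine excursions of amplitude 60–140 mg/dL peaking after
30–60 min; with probability 0.10 per meal, a dip overwriting the trajectory
90–150 min post-meal — 15-min descent to 5–15 mg/dL below the 54 mg/dL
threshold, a hold, and a 20-min recovery; AR(1) sensor noise (SD 3 mg/dL,
lag-1 coefficient 0.7); Poisson data gaps (0.3/day, 10–60 min); clipping to
the 40–400 mg/dL sensor range. The dip hold is shortened by one slot (with
a 15-min floor so every generated dip is a detectable event) to keep the
sub-54 time equal to the drawn duration once the ramp crossings are counted.
The excursion/dip waveform itself is a modelling convenience; calibration is
to cohort statistics, not to any waveform. With 47 subjects × 39 days the
defaults land at a median per-subject mean of ≈ 112 mg/dL, SD ≈ 31 mg/dL,
≈ 0.65 % of time < 54 mg/dL, ≈ 3.8 Level-2 episodes per 10 days with median
duration 25 min — inside the published interquartile ranges for mean and SD
and close to the published episode rate and duration. MAGE runs higher
(≈ 100 vs ≈ 55 mg/dL) because every simulated excursion has the full 60–140
amplitude, where real traces mix many smaller ones; the joint constraint of
episode rate and time-below-54 is approximated, not matched exactly.

All randomness flows from `(seed, subject_seed)` through an explicit
generator; cohorts are reproducible bit-for-bit, and a subject's trace does
not depend on cohort size or ordering. A clairvoyant forecaster
(ŷ(t+5k|t) = y(t+5k)) provides the perfect-information end point: on
noiseless cohorts, with AlarmLevel at 54 and PH = 25, it achieves 100 %
Recall, zero false alarms and zero MAE — the end-to-end identity the test
suite asserts.

What passing on synthetic data does *not* show: robustness to real sensor
artefacts (compression lows, calibration jumps), behavioural confounders
(exercise, alcohol, rescue carbohydrates truncating dips), circadian
structure, or inter-subject heterogeneity in meal timing. Absolute
event-based scores on synthetic cohorts are therefore not comparable to
clinical ones; the pipeline's contracts (causality, matching rules, tuning
logic) are what the suite establishes.

## Problem sizes in the test suite

Tests run at deliberately modest sizes chosen to exercise the estimators'
asymptotics without waste: AR(1) recovery at n = 1000 (20 replicates),
ARIMA recovery at n = 5000, oracle-equivalence sweeps over 100–1000 random
instances, end-to-end runs on 10-subject × 10-day noiseless cohorts and one
47-subject × 39-day default cohort for calibration.
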