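# Methods

## Problem setting

A monitored patient carries N sensors reporting n ≥ N physiological
parameters at a fixed cadence; at instant *t* the observation is the
vector A_t = (a_t,1 … a_t,n). Alarms should fire on genuine medical
deterioration and stay silent on sensor artifacts. The discriminating
physiology: deterioration is systemic and moves a majority of vitals
coherently (e.g. mean arterial pressure rising while heart rate,
pulse, respiration and SpO₂ fall), whereas an artifact is confined to
the one channel whose transducer misbehaves.

## Detection pipeline

Per parameter and instant, the pipeline keeps two sliding buffers of
accepted history (defaults: 30 samples each — long enough to estimate
a local scale, short enough to track the patient's state).

**Forecaster.** ε-SVR with linear kernel fitted per window. The
regression minimises ½‖w‖² + C·Σ(ξᵢ + ξᵢ*) with residuals outside the
ε tube penalised linearly; the solver is the SMO-type optimiser in
scikit-learn's `SVR` (the contract is the objective, not the
algorithm). Features:

* `lags` (pipeline default): the previous 3 values. A one-step
  forecast must model the signal's autocorrelation; on autoregressive
  data this attains prediction error near the innovation scale.
* `time_index` (default of the standalone `SVRConfig`, and what the
  forecaster-comparison harness uses for all three methods): the
  window-local index rescaled to [0, 1]. This treats forecasting as
  local trend extrapolation, the same problem handed to the
  linear-regression and Gaussian-process baselines, which keeps the
  comparison fair — but it cannot track the AR state and is therefore
  not used for detection.

Each window is standardised by its mean and SD before the solve, so
the optimiser sees O(1) quantities regardless of native units; the
standardisation commutes with adding a constant, making translation
equivariance exact rather than approximate. Defaults C = 1 and
ε = 0.1 × window SD (the tube scales with the parameter's own units;
an absolute ε cannot be meaningful simultaneously for SpO₂ in percent
and ABP in mmHg). Solver tolerance is 1e-9 so refits are reproducible
and equivariance holds to ~1e-6 relative.

Windows containing missing readings are skipped, never imputed — an
imputation would be a prediction compared against a prediction,
masking exactly the faults the pipeline looks for. A parameter with no
usable window abstains; the vote denominator n is the number of
non-abstaining parameters, and instants where all parameters abstain
yield no decision.

**Dynamic threshold.** T_d = k·S_d with S_d the sample SD (n−1
denominator) of the threshold buffer and k = 1. S_d is a *scale of
normal variability for this patient right now*; a residual exceeding
it is surprising relative to recent history. The comparison uses the
native-unit residual |S_a − S_p|, not the percentage error, because
T_d itself is in native units; the percentage error is computed and
logged on every record for reporting. A frozen variant T_f (SD of the
initial window, never updated) is retained as the fixed-threshold
special case; `threshold_mode_comparison` runs both and on drifting
data shows the frozen threshold going stale (it inflates false
positives when the patient's variability regime changes after the
calibration window).

**Buffer update policy.** After each decision the sensed value is
pushed into both buffers (`accept_all`, the default) — estimates never
replace measurements. The alternative `accept_normal_only` pushes the
prediction instead of a flagged reading, which quarantines anomalies
from the model of normality but is an unstable positive feedback: once
a parameter flags persistently the forecaster predicts its own
predictions, the buffers decouple from the data, and flagging becomes
an absorbing state (observed on clean data: flag rate reaches 1.0
within ~50 samples). It remains available as an explicit option for
experimentation, not as the default.

**Majority vote.** Y = Σ v(i). Y = 0 → normal; Y > n/2 → true alarm;
otherwise false alarm (sensor anomaly). "Majority" is strict: with
n = 5, three parameters must corroborate. An even-n tie (Y = n/2)
resolves to false alarm — a split vote is not treated as a
corroborated emergency. A verdict of `normal` is emitted when no
parameter exceeds its threshold, so every decided instant carries
exactly one of three verdicts.

## Evaluation

Scoring is event-level by default: each ground-truth event contributes
one outcome. A medical event is a true positive if any instant in its
window is declared a true alarm, else a false negative; a fault window
declared true alarm anywhere is a false positive, else a true
negative. This matches how alarm systems are audited — per alarm
candidate, not per sample. Instant-level scoring is available for
diagnostics. DR = TP/(TP+FN), FPR = FP/(FP+TN); undefined ratios
(empty denominator) are reported as missing (NaN), never silently 0.

ROC-style operating points come from re-running detection on the first
k parameters in canonical order (ABPmean, HR, Pulse, Respiration,
SpO₂) for k = 1…n: fewer voters weaken corroboration, tracing the
DR/FPR trade-off.

## Synthetic data generator

The generator emulates MIMIC-style numerics (per-second derived
vitals), not waveforms. Each parameter is

x_t = μ + d_t + r_t

* μ — baseline, inside normal resting-adult ranges: ABPmean 85 mmHg,
  HR 80 bpm, Pulse 80 bpm, Respiration 16 /min, SpO₂ 97.5 %.
* d_t — slow physiological wander: three incommensurate sinusoids
  (base periods 90/200/460 samples, seeded random phases, ±15 % period
  jitter, weights 0.6·0.85ⁱ) scaled by a per-parameter amplitude
  (HR 5 bpm, ABPmean 6 mmHg, Respiration 1.8 /min, SpO₂ 1.2 %). Three
  tones rather than one: a single tone leaves long flat-top stretches
  where the stream is unrealistically quiet and any threshold
  estimated from it collapses. A shared latent wander component with
  loading √|c|, c = `cross_correlation` = 0.3, correlates the slow
  components across parameters — co-regulation of vitals is a
  minutes-scale phenomenon.
* r_t — AR(1) noise, r_t = φ·r_{t−1} + e_t, φ = 0.9, innovation SDs
  0.4/0.3/0.3/0.12/0.08 native units (monitor numerics average over
  several beats, so sample-to-sample jitter is small), independent
  across parameters. Started at the stationary distribution, so there
  is no burn-in transient; the closed-form stationary SD
  σ/√(1−φ²) is the oracle for the generator's moment tests.

The drift-to-noise amplitude ratio (~15) is harmonised across
parameters and puts the clean-data per-parameter flag rate near 5 % at
k = 1 — the regime in which a dynamic SD threshold is informative. All
vitals are clipped at 0 and SpO₂ at 100 %. Negative
`cross_correlation` loads the shared component with alternating signs
(an all-pairs-negative correlation is unrealisable with one factor).

**Events.** `inject_event` multiplies affected values by
(1 + direction·m), m ∈ {0.20, 0.30, 0.50}, over a window, or zeroes
them (`dropout`, the oximeter-disconnect signature); instants outside
the window are untouched bit for bit, and overlapping events are
rejected. `make_benchmark` places medical events (all five parameters
co-perturbed with the deterioration signature: ABPmean up, the rest
down) and single-parameter faults (cycling through parameters,
alternating sign) uniformly at random outside a 60-sample warm-up with
a 10-sample minimum gap, default duration 8 samples.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: measurement quantisation, missing-data
bursts and artifact shapes other than multiplicative steps and
dropouts (spikes, saturation, slow drift-type faults), patient-state
regime changes (sleep/wake, medication), inter-patient variability,
and genuinely pathological dynamics. Real HR/Pulse pairs are also far
more tightly coupled than the shared-factor model produces.

## Numerical choices and degenerate inputs

* Flagging is strictly greater-than: a residual equal to T_d is not a
  flag, so a zero-variance window (T_d = 0) flags any nonzero residual
  but a constant series flags nothing.
* Sample SD uses the n−1 denominator; a buffer of fewer than 2 values
  has S_d = 0.
* Non-finite values are rejected by threshold updates (state
  unchanged) and by `fit_window` (fit error); a missing sensed value
  makes the parameter abstain and clears its prediction window, which
  then refills over the next 30 samples.
* Percentage error at S_a = 0 is stored as missing and excluded from
  percentage-error means (the excluded count is reported); zero SpO₂
  readings are real data (probe dropout), never treated as missing.
* Determinism: one `numpy` Generator per simulation seeded from the
  user seed; the SVR solve is deterministic at fixed tolerance; two
  identical runs produce byte-identical outputs.

## Problem sizes

The packaged benchmark uses 1,000 samples × 5 parameters with 15
events, a size at which the full pipeline (≈4,850 window fits) runs in
seconds while leaving every event window surrounded by generous normal
context; the acceptance script's sweeps reuse streams of 200–1,000
samples and 100 rolling forecasts per method and parameter.

## Known limitations

* The per-window SVR refit is O(length × parameters) small QP solves;
  a production system would update the model incrementally.
* With k = 1 fixed and event-level scoring over 10 fault windows, the
  benchmark FPR is 0 for most seeds but can reach 0.1–0.2 on unlucky
  ones (coincident marginal flags on two extra parameters inside a
  fault window); the acceptance property is stochastic in exactly the
  way the per-parameter flag rate implies.
* The voting rule weighs all parameters equally; HR and Pulse measure
  the same physiology through different transducers, so a true cardiac
  event effectively gets two votes while a respiratory one gets one.
* Thresholds adapt within ~30 samples of a regime change; an event
  longer than the threshold window inflates S_d and partially masks
  its own tail (the flag is raised at onset regardless).
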