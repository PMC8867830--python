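# Methods

## Problem

In infrared-marker hybrid real-time tumor tracking, the treatment machine
cannot image the tumor continuously.  Instead, reflective markers on the
abdominal wall are tracked at 60 Hz (the external surrogate signal
`P_IR`, 1-D vertical displacement in mm), while an orthogonal kV imaging
subsystem detects implanted fiducials — the internal 3-D target position
`P_detect` (right–left, superior–inferior, anterior–posterior; mm) — only
every 80–640 ms.  A prediction model maps the surrogate to the target so
the beam can follow it between detections.  Models are built per session
from a 20–40 s recording: the first three quarters are the training
period, the last quarter the testing period.

`tumortrack` implements three predictors and the statistics used to
compare them:

1. **Quadratic regression** (the clinical baseline):
   `f(P_IR, v_IR) = a P_IR² + b P_IR + c + d v_IR² + e v_IR`, one
   independent OLS fit per anatomical direction (15 coefficients), with
   marker positions extrapolated 25 ms forward from their causal velocity
   to offset system latency.
2. **CNN with transfer learning**: a 19-layer 1-D convolutional network
   (8 conv, 5 batch-norm, 3 dropout, 1 flatten, 2 dense) trained once on a
   historical cohort (20 epochs, Adam, lr 0.001, mean-absolute-error loss
   in mm) and fine-tuned per session (5 epochs, lr annealed linearly
   5e-4 → 1e-4).
3. **Sugeno ANFIS with pattern search**: per marker and direction, greedy
   forward selection keeps 5 of 19 lagged marker positions
   ({0…10, 15, 20, …, 50} samples behind the detection time), then a
   first-order Sugeno fuzzy system seeded by subtractive clustering is
   hybrid-trained for 4 epochs (exact least-squares consequents +
   normalized gradient steps on the Gaussian memberships).

CNN and ANFIS predictions are arithmetic means over the per-marker
outputs.

## Synthetic respiratory sessions

The clinical recordings are not publicly available, so the simulator
generates surrogate sessions calibrated to reported clinical
cohort summaries.

**Latent breathing signal.** Per cycle k,
`b(t) = −A_k · sin(π (t − t_k)/T_k)^m` with m = 4 (Lujan-type power-of-
cosine family, phase-shifted so cycle boundaries sit at the b = 0 dwell
and the concatenated signal is continuous under per-cycle jitter).
Defaults: A ~ 7.2 mm, T ~ 4.2 s with 5 % per-cycle jitter.  The exponent
m = 4 was fixed from the reported speed statistic: the dense numerical
90th-percentile speed of the mean-parameter waveform is 6.8 mm/s, inside
the reported 7.3 ± 2.0 mm/s band (m = 2 gives 5.3, m = 6 gives 8.1).
Optional linear baseline drift and a deep-inhale event (amplitude ramped
by a multiplier > 1 late in the recording) model irregular breathing.

**Markers.** Each of the ≥ 4 markers is `gain_i · b(t) + ε`, gain ~
U(0.8, 1.2), ε white Gaussian with sd 0.1 mm (clinical summaries report no
noise floor; 0.1 mm is a plausible optical-tracking figure, exposed in
config).

**Internal target.** Per direction,
`target_d(t) = g_d · b(t − τ_d) + q_d · b(t − τ_d)² + ε`, sampled at
uniform-random detection gaps in [0.08, 0.64] s, ε sd 0.2 mm.  The lag τ
(~0.08–0.32 s) and quadratic distortion q are deliberate model mismatch:
a linear instantaneous coupling lies inside the regression baseline's
model class (a property the tests exploit), so it would mask any benefit
of the learned models; the lag and curvature are exactly the
external↔internal discrepancy the learned models can represent and the
quadratic baseline cannot (its velocity term compensates a pure delay
only to first order).  Hysteresis beyond a pure delay is not modelled.
Per-file gains are sampled so the target ranges track the reported
per-direction range distributions (SI dominant, 16.4 ± 8.1 mm).

**What the simulator does not emulate**: cardiac superposition, imaging
and segmentation artefacts in `P_detect`, couch shifts, non-stationary
coupling within a session, and marker-specific phase offsets.  Passing
tests therefore demonstrate correct algorithms and the qualitative
model ordering under calibrated breathing statistics — not clinical
accuracy magnitudes.

## CNN details

**Inputs per (marker, prediction time t).** Three streams: 12 s of the
marker trace (720 samples), 25 detected 3-D target positions at equal
time intervals over the same window (nearest detection to each grid
time), and the 50 marker samples immediately before t.  They are fused
as 5 channels of one 720-tick stack (context targets linearly resampled
per axis; the recent window right-aligned and zero-padded), keeping the
network purely convolutional until the head.

**Standardization.** Each example is affinely standardized: marker
channels by the context-IR mean/std, target channels per axis by the
context-target mean/std.  The per-axis transform is inverted at the
output and the MAE loss is computed in mm, so the externally specified training
protocol (MAE in mm) is unchanged.  This factors the patient-specific amplitude and
coupling gain out of the network's job — the key to one reference
network serving every patient — and makes the predictor exactly
invariant to couch translations.

**Context windows and causality.** A label time must never fall inside
its own context window: the 25-point context-target channel would
contain the answer and the network learns to copy (observed directly —
fine-tuning with a context frozen at the training-period tail, which can
overlap the label times, made test error
worse than the untuned reference).  Contexts are therefore frozen
*before* the labels they train: reference examples pair the
training-tail context (two shifted copies, 0 and 2.5 s back) with
testing-quarter labels; fine-tuning uses five context windows spaced 1 s
apart ending early enough to leave a causal gap the size of the testing
horizon.  Prediction conditions on the same frozen contexts the ensemble
was tuned with, averaging the newest three.

**Fine-tuning stability.** Batch-norm statistics are frozen during
fine-tuning (layers still train their affine parameters): a session
contributes only a few dozen highly correlated examples, and letting
batch statistics overwrite the cohort-level running statistics corrupted
them measurably.  Two fine-tuned copies differing only in shuffle and
dropout streams are averaged — a small ensemble that reduces the
dropout-seed variance of the 40-step adaptation.

**Architecture hyperparameters** (the 8/5/3/1/2 layer census is the
contract; the rest is free): kernel widths 7/5 alternating, strides
(4,1,2,1,2,1,2,1), channels (16,16,32,32,32,32,32,32), ReLU, dropout
0.25 after conv blocks 2–4, dense 96 → batch-norm → dense 3, He
initialization, batch 32.  Widths and the dense size were chosen by
measuring held-out error on synthetic sessions; narrower stacks
underfit.  Training is plain numpy with im2col convolutions and manual
backpropagation — single-threaded and bit-deterministic given the seeds
(verified by identical loss trajectories across runs).

## ANFIS details

Subtractive clustering (Chiu): potentials with α = 4/r², squash factor
1.25, accept/reject ratios 0.5/0.15, on min–max-normalized joint
input–output data; radius 0.5 by default.  One rule per cluster;
Gaussian membership widths `r · span/√8`.  Two numerical safeguards
beyond the textbook algorithm, both forced by the correlated lag inputs:

* **Rule cap.** Each first-order consequent carries d+1 parameters;
  with ~60 training rows and 5 inputs, uncapped clustering yields 8–10
  rules ≈ 50–60 parameters — the consequent solve enters the
  interpolation regime, coefficients explode, and testing-period
  extrapolation diverges.  Rules are capped at
  `⌊n_rows / (3 (d+1))⌋` (≥ 3 rows of support per parameter).
* **Conditioned LSE.** The consequent normal equations carry a tiny
  Tikhonov term (10⁻¹⁰ of the mean Gram diagonal; escalated to 10⁻⁸
  with a warning when the system is singular).  The single-rule
  linear-target exactness check (< 10⁻⁸ total squared error after one
  epoch) still passes.

Hybrid epoch order: solve consequents exactly → log the total squared
error → one normalized gradient step on centers/widths (step length
0.01 × mean input span, grown ×1.1 on improvement, rejected and halved
on deterioration — making the logged trajectory non-increasing by
construction).  A final consequent solve follows the last epoch.
Normalized firing strengths are computed in log space (softmax form), so
queries far outside the training hull degrade to the nearest rule
instead of 0/0.

The pattern search trains each candidate for 1 hybrid epoch (the LSE
step already optimizes consequents exactly); the final model gets the
stated 4.  Ties break toward the smaller lag.  Greedy selection equals
exhaustive subset search when the generating lags are identifiable from
single-lag prefixes (verified against full enumeration in the tests);
with strongly correlated candidates the greedy first pick can differ —
inherent to sequential forward selection.

## Evaluation statistics

3-D positional error is the Euclidean norm of `P_predict − P_detect`;
per-session trueness/precision are the mean absolute 3-D error (MAE) and
its sample (n−1) standard deviation; models are ranked per session by
MAE + 2 SD and overall by the percentage of predictions within 2 mm.
Breathing statistics: extrema located on a 0.5-s moving average with a
20 %-of-span prominence floor, refined on the raw trace within ±0.25 s
(so smoothing does not bias the range); the period uses whichever
extremum family is richer (short testing windows often expose only one
interior peak); the range averages adjacent peak–trough differences.
v90 is the 90th percentile of the absolute Savitzky–Golay derivative
(0.25 s, quadratic) — raw 60 Hz differencing would amplify 0.1 mm marker
noise to ~4 mm/s and is not usable; the smoothed estimator stays within
2 % of the dense analytic oracle on noiseless waveforms.  Relative
training→testing changes are `δ = |value_test/value_train − 1|`; on
testing windows too short to expose two cycles the deltas are reported
as NaN rather than fabricated.  The paired t-test on per-session MAE is
two-sided; an all-zero difference vector is reported as p = 1 with a
degeneracy flag.

## Problem sizes and determinism

The benchmark defaults are 30 historical and 10 evaluation sessions
(clinical-scale cohorts of ~1000/76 are config-reachable).
At this scale the full workflow — simulation, reference training,
per-session fitting of all three models, scoring — runs in about six
minutes on one CPU and is bit-for-bit reproducible from a single master
seed: every stage draws its seed from a `SeedSequence` tree, and run
directories store config, seeds and versions alongside the reports.

## Known limitations

* The CNN reference is trained on sessions from the same parametric
  family the evaluation sessions come from; transfer across genuinely
  different coupling families is untested.
* Deep-inhale irregularity (the large-δ_r scenario) is generated but the
  default benchmark cohorts are stable-breathing; all three models
  degrade on irregular files, as in the clinical report.
* The ANFIS pattern search is greedy; it matches exhaustive search only
  when the informative lags are greedily identifiable.
* Sample sizes of 10 evaluation sessions make the paired t-test
  marginal for small true differences; clinical-scale cohorts (n ≈ 76) give
  it far more power.
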