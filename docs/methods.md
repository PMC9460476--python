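# Methods

## Problem

Lower-limb pattern recognition predicts the upcoming gait activity (walk,
stair ascent/descent, ramp ascent/descent, sit/stand) from a short window of
EMG and mechanical sensor data ending just before each gait event (initial
contact). Classifiers trained once degrade over days — *concept drift* —
because skin conditions, sensor placement and user behaviour change the
input distribution. `driftadapt` implements and compares adaptation
strategies that retrain the predictor on-line from its own stream, without
ground-truth labels, and provides a synthetic multi-day data generator and a
streaming evaluation protocol to study them.

## Predictors

**Forward predictor.** A *mode-specific* classifier bank: one classifier per
current activity ("mode"), each defined over only the activities reachable
from that mode under the measurement circuit. Inputs are 300 ms pre-event
windows; per EMG channel the features are mean absolute value, zero
crossings, slope-sign changes, waveform length and 4th-order Burg
autoregressive coefficients; per mechanical channel, the mean, population
SD, max, min, start and end values (8 EMG + 20 mechanical channels gives a
184-dimensional vector). A mode with a single observed successor gets a
constant predictor (posterior 1, entropy 0).

**Backward predictor.** A single classifier over all activity classes that
labels the *completed* stride from mechanical features only, computed over
the stride interval capped at its most recent 1500 ms. Its labels serve as
pseudo-labels for forward-predictor updates.

Each classifier is a one-hidden-layer softmax network (20 rectified-linear
units) trained with Adam at step size 0.001 for at most 100 epochs,
minibatch 8, with early stopping on a stratified 10% validation split:
training stops after 3 epochs in which neither the validation error rate
nor the validation cross-entropy improves, and the best epoch's weights are
restored. Three of these choices are deliberate departures from the naive
regimen and matter on small per-mode pools (tens of samples):

* *minibatch 8* (not the conventional 32): with a fixed 100-epoch budget,
  batch 32 gives a 60-sample pool under 200 Adam steps, which demonstrably
  underfits a trivially separable two-class problem (8% vs 4% error);
* *stratified validation split*: an unstratified 10% draw from a small pool
  can be single-class, making a degenerate epoch unbeatable and causing the
  restore-best rule to return garbage weights;
* *loss-aware patience*: on tiny validation splits the error rate is
  quantized; requiring both the error *and* the loss to stall before
  stopping prevents termination while the network is still learning.

Features are z-scored with statistics refit on the training pool at every
(re)training. Retraining is always from scratch with a fresh seeded
initialization.

## Adaptation strategies

Five strategies share one retrain scheduler (retrain after every 2 trials;
a scheduled retrain is skipped when the pool has not grown):

| strategy | pool update rule |
|---|---|
| `baseline` | never update |
| `perfect` | add every streamed sample with its true label (upper reference) |
| `entropy` | add (forward features, *predicted* label) iff posterior entropy `E < Thr(N)` |
| `backward` | add (forward features, backward-predicted stride label) unconditionally |
| `backward_entropy` | as `backward`; additionally the backward predictor's own pool grows with entropy-gated (stride features, backward label) pairs, and the backward predictor retrains on the same 2-trial schedule |

The entropy gate uses `Thr(N) = 0.6/ln(5) · ln(N)` where `N` is the class
count of the deciding classifier (the mode's successor count for the
forward gate; the full activity-class count for the backward gate).
`Thr(5) = 0.6` exactly; the implementation computes `0.6 · ln(N)/ln(5)` so
the reference point is bit-exact. Selection uses strict inequality, so
single-class modes (`E = 0 = Thr(1)`) never contribute. In `backward`,
*all* backward labels update the forward pool — the entropy gate of
`backward_entropy` applies only to the backward predictor's own pool.
Backward-relabeled samples whose label falls outside their mode's frozen
class list cannot be represented by that mode's classifier and are dropped
at retrain time (logged).

## Streaming evaluation protocol

Predictors are initially trained on the first 50% of day-1 trials
(chronological split; a random split is available but breaks streaming
realism). The remaining trials stream in order: every event in a trial is
predicted with the current predictors, then the trial is handed to the
strategy, then the scheduler may retrain. Every pool entry records the
trial at which it was added; `verify_causality` checks per run that no
event entered a pool before being predicted (initial training data is never
streamed, hence never tested). The error rate is wrongly classified samples
over total samples, reported per day, per day-and-activity (conditioned on
the true label), and as a running per-trial curve. Drift is visualized by
PCA fitted on day-1 features only, with all days projected on those two
components and summarized by per-day means and 1-SD covariance ellipses.

## Synthetic data generator

The generator emulates the structure of a multi-day circuit measurement:
4 measurement days (1, 2, 3, 7), 40 trials/day by default, and a fixed
circuit — stand up, walk, stairs up, walk, ramp down, walk, ramp up, walk,
stairs down, walk, sit — yielding 24 gait events per trial (960 samples per
day, matching the ~956 ± 70 of the real recordings it mimics). Event labels
follow the transition convention that each event carries the *upcoming*
activity; an event's mode is the previous event's label.

At the feature level each event draws its forward and backward vectors from
class-conditional Gaussians (7 classes, one-hot means separated 3.2 noise
SD in 7 dimensions — chosen to put day-1 error in the mid-single-digit
percent range typical of this task). Concept drift is an additive per-day
global mean shift plus a multiplicative covariance scale: shifts
(0, 2.5, 2.8, 3.0)·u along a fixed unit direction and scales
(1.0, 0.9, 0.85, 0.85), so the largest mean jump is day 1→2 and the
largest variance is on day 1, with a near-plateau afterwards. The backward
feature space drifts along its own direction at 0.6× the forward
magnitude: full-stride summaries degrade more gently than the pre-event
window, matching the relative error growth reported for backward versus
forward predictors on real data. The first event of every trial has no
preceding stride and therefore no backward vector.

A raw-signal generator exists to exercise the conditioning and
feature-extraction stages: EMG channels are 20–450 Hz band-limited noise
amplitude-modulated by stride-locked, class-dependent envelopes; mechanical
channels are class-dependent periodic waveforms plus white noise; gait
events are *emitted*, not detected (event detection from kinematics is out
of scope). The generator does not attempt biomechanically realistic EMG,
IMU orientation dynamics, or between-subject variability beyond the seed.

**What passing tests do and do not show.** The synthetic streams reproduce
the *structure* of multi-day drift (class-conditional distributions, a
day-boundary shift, a stable circuit grammar) but not its texture: real
drift is continuous within a day, class-dependent, and non-Gaussian, and
real features are correlated across channels. Results here validate the
machinery and the qualitative strategy ordering, not clinical error rates.

## Signal conditioning contract

Resample to 1000 Hz (polyphase), then zero-lag 2nd-order Butterworth
high-pass at 20 Hz on EMG channels only (`filtfilt`, so the magnitude
response is squared and net phase is zero), then divide each EMG channel by
its maximal-voluntary-contraction reference (caller-computed; a helper
takes the peak of the rectified, 2 Hz low-pass-smoothed MVC recording).
Both conditioning steps are linear per channel, so their order does not
affect the result beyond numerical noise. Forward windows are half-open —
they end one sample *before* the event, so prediction is strictly causal.
Stride windows keep the most recent 1500 ms when a stride is longer,
because late-stride mechanics are most informative of the imminent
transition.

## Numerical and degenerate-input choices

* Entropy uses the convention 0·ln 0 = 0 and validates simplex inputs to
  1e-6; posteriors sum to 1 within 1e-9 by construction (softmax).
* Zero-variance feature columns standardize with divisor 1 (no NaNs).
* The AR fit centers the window and returns zeros for constant windows.
* Zero-crossing/slope-sign deadband defaults to 0 and is configurable.
* Covariance inputs are validated symmetric PSD; sampling adds 1e-12
  jitter before Cholesky so semi-definite inputs remain factorable.
* Pool caps are off by default (pools grow without bound, as in the
  protocol being modelled); an optional FIFO cap addresses the computational
  load concern of long deployments.

## Problem sizes used by the test suite and acceptance script

Full-protocol checks simulate 4 days × 16 trials/day × 24 events with the
default drift model, 10 seeds for the strategy-ordering and
backward-adaptation checks and 20 seeds for the zero-drift null; the
acceptance script averages 5 seeded runs of all five strategies at the same
scale. These sizes were chosen so the whole suite runs on a single CPU in
minutes while keeping every per-mode training pool large enough for the
classifiers to be non-degenerate.

## Known limitations

* The drift model is a two-parameter caricature (global shift + scale);
  real drift can rotate covariances and move classes differentially.
* Mode class lists are frozen from the initial training data; a transition
  never seen on day 1 can never be predicted later.
* The validation split is redrawn at each retraining (the alternative —
  freezing one split — is not implemented).
* Statistical comparison of strategies (repeated-measures ANOVA and
  post-hoc tests) is out of scope; the per-run tables are emitted for any
  stats package to consume.
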