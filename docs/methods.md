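# Methods

`armuse` quantifies *functional* upper-limb use — task-specific arm movement,
as opposed to incidental movement such as arm swing while walking or
gesticulation while talking — from bilateral wrist accelerometers, and
validates two estimation methods against a frame-level video-annotation
ground truth:

1. the **counts-threshold baseline**: raw acceleration → per-second activity
   counts → a second is "active" when the count magnitude exceeds 1;
2. the **epoch-feature classifier**: 4-s epochs → 11 features → a random
   forest predicting functional / non-functional per epoch.

This note documents the models, the parameters that matter, the synthetic
study conditions, the numerical choices, and what the tests do and do not
demonstrate.

## Processing chain

**Axis convention.** Device-native axes are remapped into an anatomical frame
by a signed permutation (an isometry — the per-sample Euclidean norm is
untouched): x vertical along the forearm (cranial positive), y medio-lateral
(medial positive on the right hand, lateral on the left — the wrists are
mirror images), z anterior–posterior (anterior positive). The mapping is a
named, configurable "mounting map" because it depends only on how the case is
strapped to the wrist.

**Synchronization.** The two sensors and the annotation timeline are aligned
by a calibration movement (3–5 fast arm flexions) performed at the start and
end of a session. Bursts are found on the 0.5 Hz-high-passed acceleration
norm (threshold 1.5 g, ≥3 bursts within a 3 s clustering window); the
right-vs-left clock lag is the argmax of the normalized cross-correlation of
the two high-passed norms inside the opening calibration window (±5 s search,
sample resolution). The closing window provides a spot-check; the difference
of the two lag estimates is reported as drift but not corrected. Everything
recorded before the first and after the second calibration event is
discarded. Two failure modes are flagged rather than guessed at: a flat
signal (no correlation peak) and a best in-range correlation below 0.6 —
with periodic burst trains the in-range argmax can land on a comb side-lobe,
so a weak peak, not just a boundary argmax, is the reliable sign that the
true shift exceeds the search range.

**Annotation.** Frame-level categories (25 fps): 0 unknown (includes the
calibration), 1 non-functional, 2 functional. Non-overlapping 4-s epochs
(100 frames) take the category held by a *strict majority* of frames,
otherwise `mixed`. Unknown epochs are always discarded; mixed epochs are
excluded by default (policy configurable: exclude / as-functional /
as-non-functional). Binary truth: functional → 1, non-functional → 0.
"Total functional minutes" = functional epochs × 4 s / 60.

**Counts.** The published activity-counts chain for 30 Hz input: the
21-coefficient IIR band-pass reconstruction filter (passband ≈0.29–1.63 Hz),
decimation to 10 Hz (mean of 3 samples), rectification, clipping at 2.13 g,
a 0.068 g deadband, quantization at the 0.0164 g ADC resolution, and
summation over 1-s epochs. The filter state is initialized to the
constant-input steady state, so any static orientation yields exactly zero
counts (the band-pass DC gain is zero) instead of a start-up ring. The
activity threshold is applied to the Euclidean magnitude of the three axis
counts (a per-axis OR mode is available); "exceeds 1" is strict.

**Features.** The 30 Hz signal is resampled to 50 Hz by per-axis cubic
splines, then per 4-s epoch (200 samples): mean and population variance of
each axis, and mean, population variance, minimum, maximum and Shannon
entropy of the per-sample norm — 11 features in a frozen order that forms
the model's signature. The entropy estimator is a 16-bin histogram over the
epoch's own [min, max] norm range, in bits, with 0·log 0 ≡ 0; a constant
epoch has entropy 0 and a uniformly bin-filling one log₂16 = 4. Min-max
scaling to [0, 1] is fit on the training corpus only, persisted with the
model, and applied with clipping; a constant fitted feature maps to 0.
Per-session fitting would leak test-session statistics into normalization.

**Classifier.** The originally deployed pre-trained model is not available,
so the package ships a retrainable surrogate with the identical feature
interface: a 100-tree random forest (a single decision tree is also offered)
with `min_samples_leaf=8` in the pipeline default. Two choices deserve
explanation:

* *Leaf size.* Fully grown trees emit mostly 0/1 posteriors, which makes any
  probability threshold inert; a modest leaf size keeps the posterior
  calibrated.
* *Operating point.* The emulated model is recall-first: it over-calls
  functional use at the cost of precision. The surrogate reproduces that
  operating point by calling an epoch functional when the forest posterior
  exceeds 0.30 (0.5 recovers a neutral argmax decision; an optional
  functional class weight biases training the same way).

Predictions are per-epoch with no temporal smoothing, hence invariant to
epoch order. The persisted bundle carries scaler, feature signature, seed,
threshold and hyperparameters, and refuses to predict on features whose
column order differs.

**Evaluation.** With functional as the positive class: accuracy
(TP+TN)/N, recall TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP),
f1 the harmonic mean of precision and recall. A zero denominator is reported
as 0.0 with an explicit `degenerate` flag (never NaN), keeping cohort
averages well-defined while staying auditable. Use summaries report total
functional minutes and the fraction of the trimmed session functionally
active, per method. Cohort mean differences are mean ± sample SD (ddof = 1)
of per-participant (method − ground truth) percent differences. The
score–accuracy association uses tie-corrected Spearman correlation (Pearson
on mid-ranks) with the two-sided t-approximation p-value — at n = 10 an
exact tie-aware permutation distribution is ambiguous and no method is
canonically fixed.

The package also carries the published per-participant tables of the
ten-participant validation cohort (demographics with the 0–100 QuickDASH
disability score, per-side metrics, per-side use summaries) as fixture CSVs,
and recomputes their printed summary rows — column averages, mean
differences, Spearman rho — from the per-participant values.

## Synthetic study conditions

Real recordings of the protocol cannot be shared, so the generator emulates
its structure: a session is an ordered schedule of blocks — calibration,
functional task bouts, walking, seated conversation — sampled at 30 Hz with
a paired 25 fps annotation track, gravity (1 g on anatomical x, the hanging
arm) plus activity-specific movement, and an adjustable right-sensor clock
lag. All waveforms are continuous-time closures, so the lag is applied by
evaluating the same scene at shifted times — exactly what a free-running
second device does. Default amplitudes (no published spectral
characterization of the activities exists; these are stand-ins chosen once):

| block | movement | key parameters |
|---|---|---|
| calibration | 3–5 half-sine flexion bursts | 2.3–2.7 g, 0.35 s, ~1 s apart |
| walking | z-axis swing, antiphase across arms | 0.9–1.1 Hz, 0.12–0.18 g, small vertical bounce |
| functional bout | band-limited sum of 8 sinusoids, all axes, both wrists correlated with per-wrist jitter | 0.5–3 Hz, per-axis RMS 0.26–0.40 g, on/off task envelope (4–9 s on, 0.3–1 s pauses), slow intensity modulation |
| quiet sitting | stillness + fidgeting + gesticulation | fidgets 0.8–2 s; gesture stretches 6–12 s drawn from the *same* waveform family and intensity as task bouts |
| all | additive sensor noise | sd 0.01 g |

The deliberate design element is the **class overlap**: conversational
gesticulation is annotated non-functional (no task involvement) yet is
statistically indistinguishable from task movement at the epoch-feature
level. Its misclassification — the false-positive supply — combined with the
recall-first operating point reproduces the validation regime observed with
real home recordings (accuracy ≈ 0.85, recall ≈ 0.99, specificity ≈ 0.7 on
the synthetic test sessions) and the characteristic ordering

    counts % ≥ classifier % ≥ ground-truth %,

with the counts baseline strictly overestimating on any session containing
walking (arm swing generates counts but no functional use). Earlier,
fully-separable versions of the generator produced symmetric classifier
errors and a near-perfect surrogate — unrepresentative of the method's
real behavior.

`incidental_movement=False` switches the confusable elements off (sitting
becomes pure gravity, walking bare arm swing) for physics sanity checks.

The default cohort experiment simulates 10 sessions of ≈5.4 min (a
compressed version of the ~25 min protocol; composition jittered ±20 % per
participant), per-session seeds fanned out as base seed + participant index,
clock lags drawn uniformly from ±2 s, trains on the first 6 sessions (both
wrists pooled) and evaluates all of them per side. These sizes keep the full
experiment at a few seconds while leaving every pipeline stage non-trivially
exercised.

**What the synthetic tests do not show.** The generator makes no claim of
biomechanical realism: no limb kinematics, no impaired-arm asymmetry, no
nonwear or idle-sleep artifacts, no video rendering. Passing tests
demonstrate that the chain is numerically correct, that the synchronizer
recovers known lags, and that the pipeline reproduces the *qualitative*
overestimation structure — not that the classifier would reach any
particular accuracy on real recordings.

## Numerical choices and degenerate inputs

* Population (divide-by-n) variance everywhere, fixed for determinism.
* Epochs are anchored at the trim start; no sliding windows; trailing
  partial epochs are dropped; feature and label epoch counts are truncated
  to the shorter of the two (they differ by at most one).
* Spline resampling uses `floor(n × 5/3)` output samples; the last output
  sample may extrapolate by less than one input interval.
* Ties in the majority vote (e.g. 50/50 frames) are `mixed`, never broken
  arbitrarily.
* Counts-chain constants (2.13 g clip, 0.068 g deadband, 0.0164 g/unit) are
  the published values; no re-tuning.
* Lag estimation is at sample resolution (no sub-sample interpolation);
  recovery error is bounded by half a sample plus windowing effects and
  observed ≤ 0.5 samples across seeds.
* All randomness flows from explicit seeds (`numpy` `SeedSequence` spawning
  for scene / left-noise / right-noise independence); identical config and
  seed give bit-identical sessions, reports and saved files.

## Known limitations

* The counts implementation follows the published chain and is verified by
  analytic properties (zero counts for static input, amplitude
  monotonicity, deadband behavior) and frozen self-regression values; it has
  not been compared number-for-number against vendor software output.
* The surrogate classifier is *not* the original pre-trained model; its
  absolute metrics on synthetic data say nothing about the original model's
  weights.
* The mixed-epoch handling of the original evaluation is unknown; the
  default (exclude) is one of three supported policies and the choice
  shifts per-session minutes by at most a few epochs.
* Native device containers (.gt3x) are out of scope; CSV is the interchange
  format.
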