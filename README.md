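# armuse

Functional vs non-functional upper-limb use from bilateral wrist
accelerometers.

Wrist-worn accelerometers are the standard tool for monitoring how much
people actually use their arms in daily life — in rehabilitation after
stroke, breast-cancer surgery, or other conditions that impair the upper
limb. The standard summary, the **activity-counts threshold** (a second
counts as "active" when the count magnitude exceeds 1), measures *movement*,
not *function*: arm swing while walking and fidgeting while talking all
count. `armuse` implements and validates the alternative: classify each 4-s
epoch as functional (task-specific arm movement) or non-functional from 11
epoch features, and score both methods against a frame-level video-annotation
ground truth.

## What is inside

* **signal_io** — CSV interchange for tri-axial acceleration (30 Hz) and
  timeline-marker annotations (25 fps); signed-permutation remap from
  device-native axes into the anatomical frame (x cranial, y medio-lateral
  mirrored between wrists, z anterior).
* **synchronizer** — detects the calibration movement (3–5 fast arm
  flexions) at both ends of a session, estimates the right-vs-left clock lag
  by normalized cross-correlation, trims to the span between the two
  calibration events.
* **annotation** — strict-majority labeling of 4-s epochs from per-frame
  categories (unknown / non-functional / functional), binary ground truth
  with a configurable mixed-epoch policy.
* **counts_method** — the published activity-counts chain (band-pass
  ≈0.29–1.63 Hz, 10 Hz decimation, rectify, 2.13 g clip, 0.068 g deadband,
  8-bit quantization, 1-s epoch sums) and the >1-count baseline.
* **feature_extraction** — cubic-spline resampling 30→50 Hz; per 4-s epoch
  the mean/variance of each axis plus mean, variance, min, max and Shannon
  entropy of the acceleration norm; train-corpus min-max scaling.
* **functional_classifier** — a retrainable random-forest surrogate (the
  originally deployed pre-trained model was never published) with a frozen
  feature signature and a recall-first decision threshold.
* **evaluation_stats** — confusion-matrix metrics, functional minutes,
  percent functionally active, cohort mean differences, tie-corrected
  Spearman correlation; plus the packaged per-participant tables of the
  published ten-participant validation cohort and recomputation of their
  summary rows.
* **synthetic_session / pipeline / cli** — a seeded simulator of the whole
  home protocol (calibration bursts, task bouts, walking, seated
  conversation with gesticulation, inter-sensor clock lag) and an end-to-end
  cohort experiment; `armuse` CLI with `simulate`, `sync`, `annotate`,
  `counts`, `features`, `train`, `predict`, `evaluate`, `run-all`.

The statistics per session and side: accuracy, recall = TP/(TP+FN),
specificity = TN/(TN+FP), precision = TP/(TP+FP), f1 (harmonic mean of
precision and recall); total functional minutes = functional epochs × 4 s /
60; percent functionally active = functional time / trimmed session time,
for ground truth, classifier and counts baseline.

## Worked example

Simulate a 10-session cohort, train the surrogate on 6 sessions, evaluate
everything per side:

```python
from armuse import PipelineConfig, run_validation_experiment

report = run_validation_experiment(PipelineConfig(n_sessions=10, n_train=6, seed=1))
test = report.metrics_table.query("split == 'test'")
print(test[["participant", "side", "accuracy", "recall", "specificity", "f1"]]
      .round(2).to_string(index=False))
```

```
participant  side  accuracy  recall  specificity   f1
      S_007  left      0.86    0.97         0.76 0.87
      S_007 right      0.86    0.97         0.76 0.87
      S_008  left      0.85    1.00         0.69 0.88
      S_008 right      0.88    1.00         0.74 0.89
      S_009  left      0.79    1.00         0.62 0.80
      S_009 right      0.86    1.00         0.74 0.86
      S_010  left      0.85    1.00         0.71 0.86
      S_010 right      0.83    1.00         0.68 0.85
```

High recall with visibly lower specificity: the classifier over-calls
functional use, because conversational gesticulation is indistinguishable
from task movement at the epoch-feature level. The use summaries show the
consequence — both accelerometer methods overestimate, the counts baseline
far more:

```python
piv = report.use_table.pivot_table(index=["participant", "side"],
                                   columns="method", values="percent")
print(piv[["ground_truth", "mlm", "counts"]].tail(4).round(2).to_string())
for (m, s), (mean, sd) in sorted(report.mean_differences.items()):
    print(f"mean difference vs ground truth, {m:6s} {s:5s}: {mean:.2f} [{sd:.2f}]")
```

```
method             ground_truth   mlm  counts
participant side
S_009       left           0.44  0.65    0.87
            right          0.44  0.58    0.86
S_010       left           0.47  0.62    0.86
            right          0.47  0.64    0.86

mean difference vs ground truth, counts left : 0.39 [0.02]
mean difference vs ground truth, counts right: 0.39 [0.02]
mean difference vs ground truth, mlm    left : 0.14 [0.03]
mean difference vs ground truth, mlm    right: 0.13 [0.03]
```

For every session and side the ordering `counts ≥ classifier ≥ ground truth`
holds — the counts threshold mistakes any movement (walking, fidgeting) for
function, while the classifier's overestimate is limited to genuinely
ambiguous movement.

The same experiment from the shell:

```
armuse run-all --seed 1 --n-sessions 10 --n-train 6 --out results/
```

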