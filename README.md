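# rumipress

Detection of cow behaviors — rumination, eating, drinking and sleeping —
from pressure time series measured in the reticulum, the cranial-most
forestomach compartment where primary contraction cycles (A-waves)
originate.

## The problem and who this is for

A healthy reticulorumen contracts in stereotyped primary cycles: a biphasic
reticular contraction during eating and most other behaviors, with a third
reticular contraction during rumination, and behavior-dependent quiet
intervals between cycles (mean ± SD of the peak-free gap: rumination
48 ± 12.1 s, eating 34 ± 12.7 s, drinking 35 ± 12.9 s, sleeping 41 ± 11.4 s,
other 40 ± 23.1 s). Researchers in precision livestock monitoring want to
read behavior — especially rumination, a core welfare indicator — straight
from a reticular pressure sensor sampled every 0.5 s.

`rumipress` implements two detectors over such data and a synthetic session
generator that emulates the contraction structure, so the whole pipeline is
testable end to end without animal recordings:

1. **Rule-based peak detection.** A sample is a *sharp peak* apex when the
   signal rises by ≥ θ within τ seconds before it and falls by ≥ θ within τ
   after it (defaults θ = 0.8 normalized units, τ = 3 s, after a 1.5 s
   moving-average conditioning). Consecutive peaks whose apices lie within
   12 s form a contraction cycle; a timepoint is classified *ruminating*
   when its trailing 75 s window overlaps a triphasic (3-peak) cycle, or a
   biphasic cycle whose span matches the running median triphasic span
   (the occasional two-peak cycle with the length of a regular three-peak
   pattern).
2. **Random-forest window classification.** The z-scored trace is cut into
   120 s windows (240 samples, 119.5 s overlap); each window yields 30
   frequency features (10 DFT magnitudes at bins 1–10, 10 periodogram band
   powers over (0, 0.1] Hz, 10 autocorrelations at lags 5–50 s). A
   one-vs-all random forest per behavior is trained with class rebalancing
   (3× up-sampling of rare classes with down-sampling of the majority) and
   validated three ways: stratified 70/30 holdout, 5-fold stratified
   cross-validation (SCV), and leave-one-animal-out (LOOA).

Performance is reported as Se = TP/(TP+FN), Sp = TN/(TN+FP),
PPV = TP/(TP+FP), NPV = TN/(TN+FN), F1 = 2·PPV·Se/(PPV+Se) and
Acc = (TP+TN)/(TP+TN+FP+FN).

## Worked example

```python
from rumipress import (BehaviorSchedule, generate_session, normalize_trace,
                       classify_rumination, confusion, metrics, interval_summary)
from rumipress.peak_detection import measure_intervals

schedule = BehaviorSchedule(
    [("eating", 1200.0), ("rumination", 1800.0), ("other", 600.0)],
    cow_id="demo",
)
session = generate_session(schedule, seed=1)          # 1 h, 7,200 samples

gaps = measure_intervals(session.trace)               # detected inter-cycle gaps
print(interval_summary(gaps, "all"))

flags = classify_rumination(normalize_trace(session.trace))
cm = confusion(flags, session.labels.labels == "rumination")
print(cm, metrics(cm).rounded())
```

Output:

```
IntervalSummary(behavior='all', mean=43.523809523809526, sd=17.116401437121123,
                median=44.0, iqr=20.0, n=63)
ConfusionMatrix(tp=3465, fp=51, tn=3549, fn=135)
{'Se': 0.96, 'Sp': 0.99, 'PPV': 0.99, 'NPV': 0.96, 'F1': 0.97, 'Acc': 0.97}
```

The 63 detected gaps mix eating (~34 s) and rumination (~48 s) intervals,
hence the pooled mean of 43.5 s. The rule-based classifier recovers the
30 min rumination block with Se 0.96 / Sp 0.99 against the generated
labels; the misses are concentrated at the session start before the first
cycle completes.

## Command line

```bash
rumipress simulate   --schedule schedule.yaml --seed 1 --out data/
rumipress features   --in data/session_cow1.csv --out features.csv
rumipress peakdetect --in data/session_cow1.csv --out flags.csv --cycles-out cycles.csv
rumipress train      --features features.csv --behavior rumination --scheme scv_5fold --seed 1 --out models/
rumipress evaluate   --pred flags.csv --truth data/session_cow1.csv --out eval/
rumipress experiment --out runs/exp1 --seed 1
```

`experiment` simulates a 4-cow cohort (4 h mixed-behavior sessions, one cow
with 20%-longer intervals to exercise between-animal variation), runs both
detectors, and writes interval summaries, a rumination performance table
with rows {Peak-detection, RF 70/30, RF SCV, RF LOOA}, a per-behavior 70/30
table, and a manifest. Fixed seeds give byte-identical outputs.

## Layout

- `src/rumipress/synthetic_data.py` — session generator (templates,
  interval distributions, multi-compartment A-wave propagation)
- `src/rumipress/signal_io.py` — session CSV I/O, label expansion, alignment
- `src/rumipress/features.py` — windowing and the 30-feature bank
- `src/rumipress/peak_detection.py` — sharp-peak rule, cycles, rumination rule
- `src/rumipress/rf_pipeline.py` — balancing, splits, one-vs-all forests
- `src/rumipress/evaluation.py` — confusion matrices, metrics, summaries
- `src/rumipress/experiment.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — models, parameters, numerical conventions, limitations
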