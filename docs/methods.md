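# Methods

## Signal model

The generator treats a session as a piecewise-stationary process: a
schedule of behavior segments, each filled with primary contraction cycles
separated by peak-free gaps.

**Cycle shape.** One cycle is a train of Gaussian pressure bumps
(amplitude 1.0 device unit with ±10% per-peak multiplicative jitter, FWHM
2.0 s, apices 4.0 s apart). Rumination cycles carry three bumps, every
other behavior two — the third reticular contraction is the physiological
signature of rumination. The cycle boundary is placed 1.5 × FWHM outside
the outer apices, where a Gaussian has decayed to ~0.2% of its apex; the
"cycle span" and the "peak-free gap" are defined against that boundary.
Published strip-chart figures show the contraction shape only
qualitatively; the Gaussian choice is the package's own, and nothing
downstream depends on the exact profile beyond "smooth, seconds-wide,
sharp relative to noise".

**Inter-cycle intervals.** Gaps between the end of one cycle and the start
of the next are drawn i.i.d. from a truncated Normal (floor 5 s) with
behavior-specific mean/SD defaults: rumination 48/12.1, eating 34/12.7,
drinking 35/12.9, sleeping 41/11.4, other 40/23.1 seconds. The interval is
the *peak-free time*, not apex-to-apex — the two conventions differ by one
cycle span and are not comparable across studies. Field tables report
mean/SD and median/IQR but no distributional family; the mild skew implied
by median < mean for some behaviors is not modeled (a Normal keeps one
interpretable parameter pair per behavior). Each behavior segment starts
with one fresh gap draw, as if a cycle had ended at the boundary, and a
cycle that would straddle a segment end is dropped — so no cycle crosses a
behavior change.

**Noise.** Baseline level 10 device units, plus a Gaussian random walk
(per-sample SD 0.002) emulating slow baseline wander, plus white
measurement noise (SD 0.05). At 4 h these give a baseline wander comparable
in magnitude to the contraction amplitude but far slower, which is exactly
the regime the rise-within-timespan detection rule is designed for.

**Multi-compartment propagation.** Optionally, the reticular cycle train is
copied to the cranial, dorsal and ventral rumen compartments with
non-decreasing lags (defaults 0, 3, 8, 14 s) and independent noise,
emulating the cranio-caudal A-wave. This is a generator-side option only;
all detection operates on the reticulum trace.

**What the generator does not emulate.** Secondary (B-wave) eructation
contractions, disease states (stasis, acidosis), diet and yield effects,
amplitude differences between behaviors, autocorrelated gap sequences, and
any within-cycle shape difference between eating and non-eating biphasic
cycles. Consequently, passing tests show that each algorithm recovers the
structure the generator encodes (cycle multiplicity, interval statistics,
spectral signatures) — not that it would reach the same performance on
recorded animal data, where shape variability and artifacts are richer.

## Peak-detection algorithm

Input is the per-session z-scored trace (population SD). Detection on raw
traces is available (`--raw`) but makes the threshold scale-dependent; the
historical analogue of that choice produced false positives from noise.

1. **Conditioning.** 1.5 s moving average. This is deliberately below the
   2 s contraction FWHM: contractions pass nearly unattenuated while
   single-sample noise spikes — narrower than any physiological event —
   can no longer satisfy the rise/fall rule. Set `smoothing_window=0` to
   apply the bare rule.
2. **Sharp peaks.** Sample *m* qualifies when the signal rises by
   ≥ `rise_threshold` (0.8) somewhere within the trailing
   `rise_timespan` (3 s) and falls by the same amount within the leading
   3 s. Qualifying samples closer than `apex_merge_span` (1 s) belong to
   one apex (noise can briefly interrupt a qualifying run at the top of a
   bump); the apex is the earliest maximum of the run. Onset and offset
   are the earliest minima of the trailing/leading 3 s windows — for an
   isolated bump these sit where the signal leaves/returns to baseline.
   Ties break toward the earlier sample throughout.
3. **Cycles.** Maximal runs of peaks with consecutive apex gaps
   ≤ `max_intra_cycle_gap` (12 s; intra-cycle spacing is ~4 s, inter-cycle
   gaps tens of seconds). Cycles with 2–4 peaks are considered
   physiological; singletons (isolated noise) and longer runs (rare merges
   when a gap draw falls near the floor) are excluded from interval
   statistics and classification.
4. **Rumination rule.** Per 0.5 s timepoint, with a trailing 75 s window: a
   timepoint is ruminating when the window overlaps ≥ 1 qualifying cycle.
   Qualifying: any 3-peak cycle; or a 2-peak cycle whose span lies within
   20% of the running median 3-peak span, active once five 3-peak cycles
   have been seen (the two-peak exception — occasionally the middle
   contraction is missing but the outer pair keeps the triphasic length).
   "Overlaps" means any intersection of the cycle's [start, end] with the
   window, so coverage holes appear only when a gap exceeds 75 s.

Intermediate per-window features (`cycle_window_features`: highest peak
time, peak value, baseline as the median of peak-free samples,
most-recent contraction interval) are exposed for inspection and audit;
the classification rule above consumes the cycle list directly.

Numerical conventions: thresholds are in normalized units; windows truncate
at the session start rather than being undefined; a flat trace yields no
peaks, an empty peak list yields no cycles, and a single cycle yields no
intervals.

## Feature bank (30 features per 120 s window)

Windows are 240 samples advancing one sample (119.5 s overlap). Each
window is mean-removed, then:

- **fft_01…fft_10** — magnitudes of DFT bins 1–10 (bin spacing 1/120 Hz).
  The contraction fundamentals (1/48 ≈ 0.021 Hz, 1/34 ≈ 0.029 Hz) fall in
  bins 2–4, so the band is informative by construction.
- **psd_01…psd_10** — mean power of the full-window boxcar periodogram in
  10 equal-width bands over (0, 0.1] Hz. The full-window periodogram
  (resolution 1/120 Hz) is used rather than a segment-averaged one: with
  120-sample segments the resolution would be 1/60 Hz and 4 of the 10
  bands would contain no Fourier bin at all. The periodogram uses density
  scaling and satisfies Parseval (Σ·df = window variance) exactly.
- **acf_05s…acf_50s** — biased sample autocorrelation at lags 5, 10, …,
  50 s, straddling every behavior's mean gap.

A zero-variance window yields the all-zero feature vector by convention
(its mean-removed signal is identically zero; autocorrelation of a
constant is defined as 0) rather than raising — flat windows can occur in
pathological synthetic input and should not abort a batch run. Each window
takes the behavior label of its final timepoint (causal: the window "ends
now"); the matched timepoint is otherwise unspecified in the source design
and this choice suits online monitoring.

## Random-forest pipeline

One-vs-all per behavior. Hyperparameters (500 trees, 5 = ⌊√30⌋ features
per split, leaf size 1) are conventional defaults, config-exposed; the
original values were chosen by AUC inspection and never published.
Predictions use the forest's averaged vote with ties going to negative
(conservative for monitoring alarms).

**Balancing.** Rare classes (drinking, sleeping) are up-sampled 3× — every
original positive kept once, the remainder drawn with replacement — with
negatives down-sampled without replacement to 1:1; common classes are
balanced 1:1 by down-sampling negatives only. Balancing is applied to the
full matrix before splitting, which matches how resampled counts are
reported downstream; the alternative ordering (balance within training
folds only) is reachable through the library API by composing
`make_split` + `balance_classes` manually.

**Validation schemes.** Stratified 70/30 holdout; 5-fold stratified CV;
leave-one-animal-out (one fold per cow). Stratification uses the
multiclass label so prevalences survive in every fold. Note that
consecutive windows overlap by 239 of 240 samples: row-level random
splitting therefore shares near-duplicate windows between train and test
and measures within-session interpolation, not generalization. This
replicates the original design and its optimistic holdout/SCV numbers; a
leakage-free `by_block=True` holdout (each cow's last 30% of windows in
time order) is provided, and on homogeneous synthetic cows its accuracy
tracks LOOA to within a few points while row-level SCV saturates near 1.

## Experiment orchestration and problem sizes

The default experiment is 4 cows × 4 h with a mixed schedule (41%
rumination, 27% eating, 18% other, 12% sleeping, 2% drinking) and one cow
generated with interval means scaled by 1.2, so LOOA sees genuine
between-animal variation. Session seeds derive deterministically from the
experiment seed (`seed·1000 + cow index`); all outputs are byte-stable
under a fixed seed.

The test suite exercises the same pipeline at reduced sizes chosen as the
package's own desk-scale defaults: 30 min sessions for unit-level checks,
five 4 h single-behavior sessions per behavior for interval recovery, five
2 h sessions for the rumination sensitivity and eating false-flag bounds, a
4-cow × 2 h cohort for the 70/30 random-forest bounds, and a 2-cow × 30 min
experiment (30 trees) for the determinism check. `scripts/acceptance.py`
uses the full 4 h × 5 seed setting for both interval-recovery targets.

## Known limitations

- The rule thresholds (0.8 within 3 s) are principled stand-ins: the
  original deployment's exact constants were never published. They are
  calibrated to the generator's contraction scale after normalization; a
  different sensor would need the config re-examined.
- The 30-feature identities (band edges, lags, tapers) are likewise the
  package's own even split; only the three methods and the count are fixed
  by the source design.
- Synthetic drinking is nearly indistinguishable from eating (both
  biphasic, 35 vs 34 s mean gaps), so per-behavior forests for drinking
  reflect that overlap rather than a pipeline defect.
- Multiclass combination of the binary classifiers, B-wave detection, and
  rumen-compartment (non-reticulum) analysis are out of scope.
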