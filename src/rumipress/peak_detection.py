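"""Rule-based rumination detection from sharp pressure peaks.

The detector mirrors how a clinician reads a reticular pressure strip:

1. **Sharp peaks.**  A sample is a peak apex when the signal has risen by at
   least ``rise_threshold`` within ``rise_timespan`` before it and falls by
   the same amount within ``rise_timespan`` after it.  Qualifying samples
   closer together than ``apex_merge_span`` belong to the same apex; the
   apex is the earliest maximum of the run.  Onset/offset are the minima of
   the trailing/leading windows around the apex.
2. **Contraction cycles.**  Maximal runs of peaks whose consecutive apices
   are within ``max_intra_cycle_gap`` form one cycle.  Cycles with 2-4 peaks
   are considered physiological contraction cycles; the peak-free time
   between the end of one cycle and the start of the next is the inter-cycle
   interval.
3. **Rumination rule.**  A timepoint is ruminating when its trailing 75 s
   window overlaps at least one triphasic (3-peak) cycle, or a biphasic
   cycle whose span matches the running median 3-peak span within a
   tolerance — the occasional two-peak cycle whose total length equals a
   regular three-peak pattern.

The detector expects a z-scored trace; running it on raw data (as the
original strip-chart rule did) makes the fixed threshold scale-dependent and
is exposed only as an explicit option in the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from rumipress.signal_io import SAMPLING_INTERVAL, PressureTrace

__all__ = [
    "PeakConfig",
    "Peak",
    "ContractionCycle",
    "detect_peaks",
    "group_cycles",
    "filter_cycles",
    "intercycle_intervals",
    "cycle_window_features",
    "classify_rumination",
    "measure_intervals",
]


@dataclass(frozen=True)
class PeakConfig:
    """Tunables of the rule-based detector (normalized pressure units)."""

    rise_threshold: float = 0.8
    rise_timespan: float = 3.0
    max_intra_cycle_gap: float = 12.0
    feature_window: float = 75.0
    two_peak_span_tolerance: float = 0.2
    min_cycle_peaks: int = 2
    max_cycle_peaks: int = 4
    apex_merge_span: float = 1.0
    smoothing_window: float = 1.5

    def __post_init__(self) -> None:
        if min(self.rise_threshold, self.rise_timespan, self.max_intra_cycle_gap,
               self.feature_window, self.apex_merge_span) <= 0:
            raise ValueError("all timing/threshold parameters must be positive")
        if not 0 < self.two_peak_span_tolerance < 1:
            raise ValueError("two_peak_span_tolerance must be in (0, 1)")
        if not 1 <= self.min_cycle_peaks <= self.max_cycle_peaks:
            raise ValueError("need 1 <= min_cycle_peaks <= max_cycle_peaks")
        if self.smoothing_window < 0:
            raise ValueError("smoothing_window must be >= 0 (0 disables)")


@dataclass(frozen=True)
class Peak:
    """One detected sharp peak."""

    onset_time: float
    apex_time: float
    offset_time: float
    apex_value: float

    def __post_init__(self) -> None:
        if not self.onset_time <= self.apex_time <= self.offset_time:
            raise ValueError("require onset <= apex <= offset")


@dataclass(frozen=True)
class ContractionCycle:
    """A set of consecutive peaks forming one primary contraction cycle."""

    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("a cycle needs at least one peak")

    @property
    def start_time(self) -> float:
        return self.peaks[0].onset_time

    @property
    def end_time(self) -> float:
        return self.peaks[-1].offset_time

    @property
    def span(self) -> float:
        return self.end_time - self.start_time

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def _as_values(trace) -> tuple[np.ndarray, float]:
    if isinstance(trace, PressureTrace):
        return trace.values, trace.start_time
    return np.asarray(trace, dtype=float), 0.0


def _rolling_min_trailing(x: np.ndarray, k: int) -> np.ndarray:
    """min over x[max(0, i-k) .. i] for each i."""
    pad = np.concatenate([np.full(k, np.inf), x])
    return sliding_window_view(pad, k + 1).min(axis=1)


def _earliest_argmin(x: np.ndarray, lo: int, hi: int) -> int:
    seg = x[lo : hi + 1]
    return lo + int(np.argmin(seg))


def smooth(x: np.ndarray, config: PeakConfig) -> np.ndarray:
    """Moving-average conditioning at sub-contraction scale.

    The window (default 1.5 s) is well below the ~2 s width of a reticular
    contraction peak, so contractions pass nearly unattenuated while
    single-sample measurement-noise spikes — narrower than any physiological
    event — can no longer satisfy the rise/fall rule.
    """
    size = int(round(config.smoothing_window / SAMPLING_INTERVAL))
    if size <= 1:
        return x
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(x, size=size, mode="nearest")


def detect_peaks(trace, config: PeakConfig | None = None) -> list[Peak]:
    """Detect sharp peaks by the rise/fall threshold-within-timespan rule.

    ``trace`` is a normalized :class:`PressureTrace` or plain array on the
    0.5 s grid; it is moving-average conditioned first (see :func:`smooth`).
    Returns time-ordered, non-overlapping peaks; a flat or sub-threshold
    trace yields an empty list.
    """
    config = config or PeakConfig()
    x, t0 = _as_values(trace)
    x = smooth(x, config)
    n = x.size
    k = int(round(config.rise_timespan / SAMPLING_INTERVAL))
    thr = config.rise_threshold

    trail_min = _rolling_min_trailing(x, k)
    lead_min = _rolling_min_trailing(x[::-1], k)[::-1]
    qualify = np.flatnonzero((x - trail_min >= thr) & (x - lead_min >= thr))
    if qualify.size == 0:
        return []

    merge = max(1, int(round(config.apex_merge_span / SAMPLING_INTERVAL)))
    breaks = np.flatnonzero(np.diff(qualify) > merge)
    groups = np.split(qualify, breaks + 1)

    peaks: list[Peak] = []
    for g in groups:
        lo, hi = int(g[0]), int(g[-1])
        seg = x[lo : hi + 1]
        apex = lo + int(np.argmax(seg))  # earliest maximum on ties
        onset = _earliest_argmin(x, max(0, apex - k), apex)
        offset = _earliest_argmin(x, apex, min(n - 1, apex + k))
        peaks.append(Peak(
            onset_time=t0 + onset * SAMPLING_INTERVAL,
            apex_time=t0 + apex * SAMPLING_INTERVAL,
            offset_time=t0 + offset * SAMPLING_INTERVAL,
            apex_value=float(x[apex]),
        ))
    return peaks


def group_cycles(peaks: list[Peak], config: PeakConfig | None = None) -> list[ContractionCycle]:
    """Group time-ordered peaks into contraction cycles.

    Peaks whose consecutive apices are within ``max_intra_cycle_gap`` belong
    to one cycle; an isolated peak forms a 1-peak cycle.
    """
    config = config or PeakConfig()
    if not peaks:
        return []
    cycles: list[ContractionCycle] = []
    current = [peaks[0]]
    for prev, cur in zip(peaks, peaks[1:]):
        if cur.apex_time - prev.apex_time <= config.max_intra_cycle_gap:
            current.append(cur)
        else:
            cycles.append(ContractionCycle(tuple(current)))
            current = [cur]
    cycles.append(ContractionCycle(tuple(current)))
    return cycles


def filter_cycles(
    cycles: list[ContractionCycle], config: PeakConfig | None = None
) -> list[ContractionCycle]:
    """Keep physiologically plausible cycles (min..max peaks).

    Singleton noise peaks and over-long merged runs are excluded before
    interval statistics or classification.
    """
    config = config or PeakConfig()
    return [c for c in cycles
            if config.min_cycle_peaks <= c.n_peaks <= config.max_cycle_peaks]


def intercycle_intervals(cycles: list[ContractionCycle]) -> list[float]:
    """Peak-free gaps: start of each cycle minus end of the previous one."""
    return [b.start_time - a.end_time for a, b in zip(cycles, cycles[1:])]


def measure_intervals(trace: PressureTrace, config: PeakConfig | None = None) -> list[float]:
    """Full pipeline: normalize -> detect -> group -> filter -> intervals."""
    from rumipress.features import normalize_trace

    config = config or PeakConfig()
    norm = normalize_trace(trace)
    cycles = filter_cycles(group_cycles(detect_peaks(norm, config), config), config)
    return intercycle_intervals(cycles)


def cycle_window_features(
    trace, cycles: list[ContractionCycle], config: PeakConfig | None = None
) -> pd.DataFrame:
    """Per-0.5 s intermediate features over a trailing 75 s window.

    Columns: ``window_end_s``, ``highest_peak`` (time of the tallest apex in
    the window), ``peak_value``, ``baseline`` (median of peak-free samples in
    the window) and ``contraction_interval`` (the most recent inter-cycle gap
    whose closing cycle starts inside the window).  Peak-dependent fields are
    NaN when no peak apex lies in the window.
    """
    config = config or PeakConfig()
    x, t0 = _as_values(trace)
    n = x.size
    wlen = int(round(config.feature_window / SAMPLING_INTERVAL))
    if n < wlen:
        raise ValueError(
            f"trace shorter than the {config.feature_window:g} s feature window"
        )
    times = t0 + SAMPLING_INTERVAL * np.arange(n)

    # baseline: rolling median of samples outside any peak's onset..offset
    masked = pd.Series(x.copy())
    for c in cycles:
        for p in c.peaks:
            i0 = int(round((p.onset_time - t0) / SAMPLING_INTERVAL))
            i1 = int(round((p.offset_time - t0) / SAMPLING_INTERVAL))
            masked.iloc[max(0, i0) : i1 + 1] = np.nan
    baseline = masked.rolling(wlen, min_periods=1).median().to_numpy()
    # a window fully covered by peaks: fall back to the raw window median
    allmed = pd.Series(x).rolling(wlen, min_periods=1).median().to_numpy()
    baseline = np.where(np.isnan(baseline), allmed, baseline)

    apex_times = np.array([p.apex_time for c in cycles for p in c.peaks])
    apex_vals = np.array([p.apex_value for c in cycles for p in c.peaks])
    order = np.argsort(apex_times)
    apex_times, apex_vals = apex_times[order], apex_vals[order]

    gaps = intercycle_intervals(cycles)
    gap_close_times = np.array([c.start_time for c in cycles[1:]])

    highest = np.full(n, np.nan)
    peak_val = np.full(n, np.nan)
    interval = np.full(n, np.nan)
    if apex_times.size:
        # running max of apex values over the trailing window, per timepoint
        lo = np.searchsorted(apex_times, times - config.feature_window, side="left")
        hi = np.searchsorted(apex_times, times + 1e-9, side="right")
        for i in range(n):
            if hi[i] > lo[i]:
                seg = slice(lo[i], hi[i])
                j = int(np.argmax(apex_vals[seg])) + lo[i]
                highest[i] = apex_times[j]
                peak_val[i] = apex_vals[j]
    if gap_close_times.size:
        gi = np.searchsorted(gap_close_times, times + 1e-9, side="right") - 1
        in_window = (gi >= 0) & (gap_close_times[np.clip(gi, 0, None)]
                                 >= times - config.feature_window)
        interval[in_window] = np.asarray(gaps)[gi[in_window]]

    return pd.DataFrame({
        "window_end_s": times,
        "highest_peak": highest,
        "peak_value": peak_val,
        "baseline": baseline,
        "contraction_interval": interval,
    })


def _qualifying_cycles(
    cycles: list[ContractionCycle], config: PeakConfig
) -> list[ContractionCycle]:
    """Cycles that signal rumination: triphasic, or the two-peak exception.

    The two-peak exception compares a biphasic cycle's span to the running
    median of triphasic spans seen earlier in the session; it activates only
    once five triphasic cycles have been observed.
    """
    out = []
    tri_spans: list[float] = []
    for c in sorted(cycles, key=lambda c: c.start_time):
        if c.n_peaks == 3:
            out.append(c)
            tri_spans.append(c.span)
        elif c.n_peaks == 2 and len(tri_spans) >= 5:
            med = median(tri_spans)
            if abs(c.span - med) <= config.two_peak_span_tolerance * med:
                out.append(c)
    return out


def classify_rumination(trace, config: PeakConfig | None = None) -> np.ndarray:
    """Per-0.5 s rumination flags for a normalized trace (>= 75 s long).

    A timepoint is flagged when its trailing 75 s window overlaps at least
    one qualifying contraction cycle (3-peak, or 2-peak by the span
    exception).
    """
    config = config or PeakConfig()
    x, t0 = _as_values(trace)
    n = x.size
    if n * SAMPLING_INTERVAL < config.feature_window:
        raise ValueError(
            f"trace ({n * SAMPLING_INTERVAL:g} s) shorter than the "
            f"{config.feature_window:g} s classification window"
        )
    cycles = filter_cycles(group_cycles(detect_peaks(trace, config), config), config)
    flags = np.zeros(n, dtype=bool)
    for c in _qualifying_cycles(cycles, config):
        i0 = int(np.ceil((c.start_time - t0) / SAMPLING_INTERVAL - 1e-9))
        i1 = int(np.floor((c.end_time + config.feature_window - t0)
                          / SAMPLING_INTERVAL + 1e-9))
        flags[max(0, i0) : min(n, i1 + 1)] = True
    return flags
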