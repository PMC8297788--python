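"""Sliding-window frequency features for behavior classification.

The pressure trace is z-scored per session, cut into 120 s windows (240
samples at 0.5 s) advancing one sample at a time (119.5 s overlap), and each
window is summarized by 30 features from three views of its frequency
content:

* ``fft_01 .. fft_10`` — magnitudes of discrete-Fourier bins 1-10 of the
  mean-removed window.  Bin spacing is 1/120 Hz, so the contraction
  fundamentals (1/48 ~ 0.021 Hz during rumination, 1/34 ~ 0.029 Hz during
  eating) fall in bins 2-4.
* ``psd_01 .. psd_10`` — mean periodogram power in 10 equal-width bands over
  (0, 0.1] Hz.
* ``acf_05s .. acf_50s`` — sample autocorrelation at lags 5, 10, ..., 50 s,
  straddling every behavior's mean inter-cycle interval.

Each window inherits the behavior label of its final timepoint (a causal
convention: the window "ends now").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from rumipress.signal_io import SAMPLING_INTERVAL, BehaviorLabels, PressureTrace

__all__ = [
    "FeatureConfig",
    "FEATURE_COLUMNS",
    "normalize_trace",
    "make_windows",
    "window_periodogram",
    "extract_features",
    "window_label",
    "build_feature_matrix",
]

_FS = 1.0 / SAMPLING_INTERVAL  # 2 Hz


@dataclass(frozen=True)
class FeatureConfig:
    """Windowing and feature-bank layout (10 FFT + 10 PSD + 10 ACF = 30)."""

    window_length: float = 120.0
    step: float = SAMPLING_INTERVAL
    n_fft_features: int = 10
    n_psd_features: int = 10
    psd_band_top: float = 0.1  # bands are equal-width over (0, psd_band_top] Hz
    acf_lags: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0,
                                   30.0, 35.0, 40.0, 45.0, 50.0)

    def __post_init__(self) -> None:
        if abs(self.window_length / SAMPLING_INTERVAL
               - round(self.window_length / SAMPLING_INTERVAL)) > 1e-9:
            raise ValueError("window_length must be a multiple of 0.5 s")
        if self.n_features < 1:
            raise ValueError("feature bank is empty")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_length / SAMPLING_INTERVAL))

    @property
    def n_features(self) -> int:
        return self.n_fft_features + self.n_psd_features + len(self.acf_lags)

    @property
    def feature_columns(self) -> list[str]:
        cols = [f"fft_{k:02d}" for k in range(1, self.n_fft_features + 1)]
        cols += [f"psd_{k:02d}" for k in range(1, self.n_psd_features + 1)]
        cols += [f"acf_{int(round(lag)):02d}s" for lag in self.acf_lags]
        return cols


_DEFAULT_CONFIG = FeatureConfig()

#: Column names of the default 30-feature bank.
FEATURE_COLUMNS: list[str] = _DEFAULT_CONFIG.feature_columns


def normalize_trace(trace: PressureTrace) -> PressureTrace:
    """Per-session z-score: mean 0, SD 1 (population SD)."""
    x = trace.values
    if x.size < 2:
        raise ValueError("normalization needs at least 2 samples")
    sd = float(np.std(x))
    if sd == 0.0:
        raise ValueError("cannot normalize a zero-variance (constant) trace")
    from dataclasses import replace

    return replace(trace, values=(x - np.mean(x)) / sd)


def make_windows(
    trace: PressureTrace, config: FeatureConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """All 240-sample sliding windows and their end times.

    Returns ``(windows, end_times)`` where ``windows`` is an ``(N-239, 240)``
    read-only view; consecutive windows share 239 samples (119.5 s overlap).
    """
    config = config or _DEFAULT_CONFIG
    w = config.window_samples
    x = trace.values
    if x.size < w:
        raise ValueError(
            f"trace has {x.size} samples; at least {w} needed for a "
            f"{config.window_length:g} s window"
        )
    windows = sliding_window_view(x, w)
    end_times = trace.start_time + SAMPLING_INTERVAL * (
        np.arange(windows.shape[0]) + w - 1
    )
    return windows, end_times


def window_periodogram(window: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full-window periodogram (boxcar, density scaling) of the mean-removed
    window.  Satisfies Parseval: ``sum(Pxx) * df == var(window)``."""
    x = np.asarray(window, dtype=float)
    n = x.size
    xm = x - x.mean()
    spec = np.abs(np.fft.rfft(xm)) ** 2 / (_FS * n)
    spec[1:] *= 2.0
    if n % 2 == 0:
        spec[-1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n, d=SAMPLING_INTERVAL)
    return freqs, spec


def _psd_band_slices(n: int, config: FeatureConfig) -> list[np.ndarray]:
    freqs = np.fft.rfftfreq(n, d=SAMPLING_INTERVAL)
    width = config.psd_band_top / config.n_psd_features
    slices = []
    for b in range(config.n_psd_features):
        lo, hi = b * width, (b + 1) * width
        slices.append(np.flatnonzero((freqs > lo + 1e-12) & (freqs <= hi + 1e-12)))
    return slices


def _features_batch(windows: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """Vectorized feature bank for a stack of windows, shape (n, w) -> (n, 30).

    Zero-variance windows yield all-zero rows by convention (the mean-removed
    signal is identically zero, and autocorrelation of a constant is defined
    as 0 here rather than raising).
    """
    w = config.window_samples
    if windows.ndim != 2 or windows.shape[1] != w:
        raise ValueError(f"windows must have {w} samples each")
    if not np.all(np.isfinite(windows)):
        raise ValueError("windows must be finite")
    xm = windows - windows.mean(axis=1, keepdims=True)
    spec_raw = np.abs(np.fft.rfft(xm, axis=1))

    fft_feats = spec_raw[:, 1 : config.n_fft_features + 1]

    pxx = spec_raw**2 / (_FS * w)
    pxx[:, 1:] *= 2.0
    if w % 2 == 0:
        pxx[:, -1] /= 2.0
    band_slices = _psd_band_slices(w, config)
    psd_feats = np.column_stack([pxx[:, s].mean(axis=1) for s in band_slices])

    var = np.einsum("ij,ij->i", xm, xm)
    safe_var = np.where(var > 0, var, 1.0)
    acf_cols = []
    for lag_s in config.acf_lags:
        k = int(round(lag_s / SAMPLING_INTERVAL))
        acf_cols.append(np.einsum("ij,ij->i", xm[:, :-k], xm[:, k:]) / safe_var)
    acf_feats = np.column_stack(acf_cols)

    out = np.hstack([fft_feats, psd_feats, acf_feats])
    out[var == 0] = 0.0
    return out


def extract_features(
    window: np.ndarray, config: FeatureConfig | None = None
) -> np.ndarray:
    """30-feature vector for one 240-sample window."""
    config = config or _DEFAULT_CONFIG
    window = np.asarray(window, dtype=float)
    if window.ndim != 1 or window.size != config.window_samples:
        raise ValueError(
            f"expected a 1-D window of {config.window_samples} samples, "
            f"got shape {window.shape}"
        )
    return _features_batch(window[None, :], config)[0]


def window_label(labels: BehaviorLabels, window_end_time: float) -> str:
    """Behavior label at a window's final timepoint."""
    idx = (window_end_time - labels.start_time) / labels.sampling_interval
    i = int(round(idx))
    if abs(idx - i) > 1e-6 or not 0 <= i < len(labels):
        raise ValueError(
            f"window end time {window_end_time} outside the label span "
            f"[{labels.start_time}, {labels.end_time}]"
        )
    return str(labels.labels[i])


def build_feature_matrix(
    sessions, config: FeatureConfig | None = None
) -> pd.DataFrame:
    """Feature matrix over sessions: one row per sliding window.

    ``sessions`` is an iterable of ``(PressureTrace, BehaviorLabels)`` pairs
    (or objects exposing ``.trace``/``.labels``, e.g. generated sessions).
    Traces are z-scored per session before windowing.  Columns: the 30
    feature columns plus ``window_end_s``, ``label``, ``cow_id``.
    """
    config = config or _DEFAULT_CONFIG
    frames = []
    for item in sessions:
        if isinstance(item, tuple):
            trace, labels = item
        else:
            trace, labels = item.trace, item.labels
        if len(trace) != len(labels):
            raise ValueError("trace and labels must be aligned (equal lengths)")
        norm = normalize_trace(trace)
        windows, end_times = make_windows(norm, config)
        feats = _features_batch(windows, config)
        df = pd.DataFrame(feats, columns=config.feature_columns)
        df["window_end_s"] = end_times
        offsets = np.round(
            (end_times - labels.start_time) / labels.sampling_interval
        ).astype(int)
        df["label"] = labels.labels[offsets]
        df["cow_id"] = trace.cow_id
        frames.append(df)
    if not frames:
        raise ValueError("no sessions provided")
    out = pd.concat(frames, ignore_index=True)
    if not np.all(np.isfinite(out[config.feature_columns].to_numpy())):
        raise AssertionError("non-finite feature values")
    return out
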