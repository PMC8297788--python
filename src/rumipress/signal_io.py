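"""Read, write and align labeled reticular pressure sessions.

A session is a regularly sampled (0.5 s) pressure series for one cow, in one
or four forestomach compartments, paired with a per-timepoint behavior label
from the closed set ``{rumination, eating, drinking, sleeping, other}``.
Sessions travel as plain CSV with columns ``time_s``, ``pressure`` (or one
``pressure_<compartment>`` column per compartment), ``label`` and ``cow_id``.
Times are multiples of 0.5 s from session start; each sample is timestamped
at the start of its interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: The closed behavior set, as scored from video observation.
BEHAVIORS = ("rumination", "eating", "drinking", "sleeping", "other")

#: Forestomach compartments in cranio-caudal A-wave propagation order.
COMPARTMENTS = ("reticulum", "cranial", "dorsal", "ventral")

#: Device sampling interval in seconds.
SAMPLING_INTERVAL = 0.5

_GRID_TOL = 1e-6


@dataclass
class PressureTrace:
    """A regularly sampled pressure series for one session and compartment.

    ``values`` are in device units (mV) for raw sessions or dimensionless
    after z-score normalization.
    """

    values: np.ndarray
    cow_id: str = "0"
    compartment: str = "reticulum"
    start_time: float = 0.0
    sampling_interval: float = SAMPLING_INTERVAL

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("trace values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if abs(self.sampling_interval - SAMPLING_INTERVAL) > _GRID_TOL:
            raise ValueError(
                f"sampling_interval must be {SAMPLING_INTERVAL} s, "
                f"got {self.sampling_interval}"
            )
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.sampling_interval * np.arange(self.values.size)

    @property
    def end_time(self) -> float:
        """Time of the last sample."""
        return self.start_time + self.sampling_interval * (self.values.size - 1)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class BehaviorLabels:
    """Per-timepoint behavior labels on a regular grid.

    Video scoring produces labels at 1 s resolution; :func:`expand_labels`
    duplicates them onto the 0.5 s sample grid of the pressure data.
    """

    labels: np.ndarray
    cow_id: str = "0"
    start_time: float = 0.0
    sampling_interval: float = SAMPLING_INTERVAL

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        unknown = set(self.labels) - set(BEHAVIORS)
        if unknown:
            raise ValueError(f"unknown behavior label(s): {sorted(unknown)}")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.sampling_interval * np.arange(self.labels.size)

    @property
    def end_time(self) -> float:
        return self.start_time + self.sampling_interval * (self.labels.size - 1)

    def __len__(self) -> int:
        return self.labels.size


def _check_grid(times: np.ndarray, path: str | Path | None = None) -> None:
    """Verify a strictly increasing 0.5 s grid, naming the offending row."""
    diffs = np.diff(times)
    bad = np.flatnonzero(np.abs(diffs - SAMPLING_INTERVAL) > _GRID_TOL)
    if bad.size:
        i = int(bad[0])
        where = f" in {path}" if path is not None else ""
        raise ValueError(
            f"irregular timestamp{where}: step of {diffs[i]:g} s between rows "
            f"{i + 1} and {i + 2} (time_s {times[i]:g} -> {times[i + 1]:g}); "
            f"expected {SAMPLING_INTERVAL} s"
        )


def write_session(
    traces: PressureTrace | dict[str, PressureTrace],
    labels: BehaviorLabels,
    path: str | Path,
) -> None:
    """Write a session CSV (one pressure column per compartment)."""
    if isinstance(traces, PressureTrace):
        traces = {traces.compartment: traces}
    first = next(iter(traces.values()))
    n = len(first)
    for tr in traces.values():
        if len(tr) != n or abs(tr.start_time - first.start_time) > _GRID_TOL:
            raise ValueError("all compartment traces must share one time grid")
    if len(labels) != n:
        raise ValueError(
            f"labels ({len(labels)}) and trace ({n}) lengths differ; align first"
        )
    data: dict[str, np.ndarray] = {"time_s": first.times}
    if len(traces) == 1:
        data["pressure"] = first.values
    else:
        for comp in COMPARTMENTS:
            if comp in traces:
                data[f"pressure_{comp}"] = traces[comp].values
    data["label"] = labels.labels
    data["cow_id"] = np.full(n, first.cow_id, dtype=object)
    pd.DataFrame(data).to_csv(path, index=False)


def read_session(path: str | Path) -> tuple[dict[str, PressureTrace], BehaviorLabels]:
    """Read a session CSV, verifying the 0.5 s grid and the label set.

    Returns a compartment-keyed dict of traces (single-compartment files map
    to ``"reticulum"``) and the aligned labels.  Extra columns are ignored.
    """
    df = pd.read_csv(path)
    for col in ("time_s", "label", "cow_id"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    pressure_cols = [c for c in df.columns if c == "pressure" or c.startswith("pressure_")]
    if not pressure_cols:
        raise ValueError(f"missing pressure column(s) in {path}")
    times = df["time_s"].to_numpy(dtype=float)
    _check_grid(times, path)
    cow_id = str(df["cow_id"].iloc[0])
    start = float(times[0])
    traces: dict[str, PressureTrace] = {}
    for col in pressure_cols:
        comp = "reticulum" if col == "pressure" else col.removeprefix("pressure_")
        traces[comp] = PressureTrace(
            df[col].to_numpy(dtype=float), cow_id=cow_id, compartment=comp,
            start_time=start,
        )
    labels = BehaviorLabels(
        df["label"].to_numpy(dtype=object), cow_id=cow_id, start_time=start
    )
    return traces, labels


def expand_labels(labels: BehaviorLabels) -> BehaviorLabels:
    """Duplicate 1 s video labels onto the 0.5 s sample grid.

    Each 1 s label covers two 0.5 s samples; output length is twice the
    input length.
    """
    if abs(labels.sampling_interval - 1.0) > _GRID_TOL:
        raise ValueError(
            f"expand_labels expects a 1 s label grid, got {labels.sampling_interval} s"
        )
    return BehaviorLabels(
        np.repeat(labels.labels, 2),
        cow_id=labels.cow_id,
        start_time=labels.start_time,
        sampling_interval=SAMPLING_INTERVAL,
    )


def align(
    trace: PressureTrace, labels: BehaviorLabels
) -> tuple[PressureTrace, BehaviorLabels]:
    """Truncate trace and labels to their common time span.

    Both inputs must be on the 0.5 s grid with start times that are multiples
    of 0.5 s, so that samples coincide exactly.  No labels are fabricated:
    the result covers only timepoints present in both inputs.
    """
    if abs(labels.sampling_interval - SAMPLING_INTERVAL) > _GRID_TOL:
        raise ValueError("labels must be on the 0.5 s grid; use expand_labels first")
    for name, start in (("trace", trace.start_time), ("labels", labels.start_time)):
        if abs(start / SAMPLING_INTERVAL - round(start / SAMPLING_INTERVAL)) > _GRID_TOL:
            raise ValueError(f"{name} start_time {start} is not on the 0.5 s grid")
    start = max(trace.start_time, labels.start_time)
    end = min(trace.end_time, labels.end_time)
    if end < start - _GRID_TOL:
        raise ValueError(
            f"disjoint spans: trace [{trace.start_time}, {trace.end_time}] vs "
            f"labels [{labels.start_time}, {labels.end_time}]"
        )
    ti = int(round((start - trace.start_time) / SAMPLING_INTERVAL))
    li = int(round((start - labels.start_time) / SAMPLING_INTERVAL))
    n = int(round((end - start) / SAMPLING_INTERVAL)) + 1
    out_trace = replace(trace, values=trace.values[ti : ti + n], start_time=start)
    out_labels = BehaviorLabels(
        labels.labels[li : li + n],
        cow_id=labels.cow_id,
        start_time=start,
        sampling_interval=SAMPLING_INTERVAL,
    )
    return out_trace, out_labels
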