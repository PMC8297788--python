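"""Synthetic reticular pressure sessions with known contraction structure.

The generator emulates the pressure signature of primary contraction cycles
(A-waves) measured in the reticulum of a healthy cow: a biphasic contraction
cycle during eating, drinking, sleeping and other behaviors, with a third
contraction during rumination.  Cycles are trains of Gaussian pressure bumps
riding on a slowly drifting baseline with white measurement noise.  The
peak-free time between the end of one cycle and the start of the next is
drawn per behavior from a truncated Normal distribution whose mean/SD
defaults are the field-reported values for each behavior (rumination 48 s,
eating 34 s, drinking 35 s, sleeping 41 s, other 40 s).

Because every cycle placed in the signal is recorded as ground truth, the
detection and classification stages downstream can be tested quantitatively
without any recorded animal data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from rumipress.signal_io import (
    BEHAVIORS,
    COMPARTMENTS,
    SAMPLING_INTERVAL,
    BehaviorLabels,
    PressureTrace,
    write_session,
)

__all__ = [
    "ContractionTemplate",
    "IntervalParams",
    "BehaviorSchedule",
    "GeneratorConfig",
    "TruthCycle",
    "SessionData",
    "default_interval_params",
    "default_template",
    "generate_cycle_waveform",
    "generate_session",
    "generate_multicompartment",
    "write_truth_cycles",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Per-behavior inter-cycle interval mean (SD) in seconds, as reported for
#: the peak-free gap between consecutive contraction cycles.
_INTERVAL_TABLE: dict[str, tuple[float, float]] = {
    "rumination": (48.0, 12.1),
    "eating": (34.0, 12.7),
    "drinking": (35.0, 12.9),
    "sleeping": (41.0, 11.4),
    "other": (40.0, 23.1),
}


@dataclass(frozen=True)
class ContractionTemplate:
    """Shape of one contraction cycle: a train of Gaussian pressure bumps.

    Parameters
    ----------
    peaks_per_cycle
        2 for the biphasic cycle (eating/drinking/sleeping/other), 3 for the
        triphasic rumination cycle.
    peak_amplitude
        Apex height above baseline, in device pressure units.
    amplitude_jitter
        Per-peak multiplicative jitter fraction; each apex amplitude is
        scaled by ``1 + U(-jitter, jitter)``.
    peak_width
        Full width at half maximum of one bump, seconds.
    intra_cycle_peak_spacing
        Seconds between successive apices within a cycle.
    """

    peaks_per_cycle: int
    peak_amplitude: float = 1.0
    amplitude_jitter: float = 0.1
    peak_width: float = 2.0
    intra_cycle_peak_spacing: float = 4.0

    def __post_init__(self) -> None:
        if self.peaks_per_cycle not in (2, 3):
            raise ValueError("peaks_per_cycle must be 2 or 3")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")
        if self.intra_cycle_peak_spacing <= self.peak_width / 2:
            raise ValueError("intra_cycle_peak_spacing must exceed peak_width / 2")
        if self.peak_amplitude < 0 or self.amplitude_jitter < 0:
            raise ValueError("amplitudes and jitter must be non-negative")

    @property
    def pad(self) -> float:
        """Seconds from cycle start to the first apex (and last apex to end).

        1.5 x FWHM puts the cycle boundary where a Gaussian bump has decayed
        to ~0.2% of its apex, i.e. effectively back at baseline.
        """
        return 1.5 * self.peak_width

    @property
    def duration(self) -> float:
        """Total cycle duration in seconds, baseline to baseline."""
        return 2.0 * self.pad + (self.peaks_per_cycle - 1) * self.intra_cycle_peak_spacing


@dataclass(frozen=True)
class IntervalParams:
    """Truncated-Normal parameters for the peak-free gap between cycles."""

    behavior: str
    mean_gap: float
    sd_gap: float
    min_gap: float = 5.0

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior {self.behavior!r}")
        if self.mean_gap <= 0 or self.min_gap <= 0 or self.sd_gap < 0:
            raise ValueError("gap parameters must be positive (sd_gap >= 0)")

    def draw(self, rng: np.random.Generator, size: int | None = None):
        if self.sd_gap == 0:
            gap = np.full(size or 1, max(self.mean_gap, self.min_gap))
            return gap if size else float(gap[0])
        a = (self.min_gap - self.mean_gap) / self.sd_gap
        return stats.truncnorm.rvs(
            a, np.inf, loc=self.mean_gap, scale=self.sd_gap,
            size=size, random_state=rng,
        )


@dataclass
class BehaviorSchedule:
    """Ordered (behavior, duration-seconds) segments for one session."""

    segments: list[tuple[str, float]]
    cow_id: str = "0"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule must contain at least one segment")
        for behavior, duration in self.segments:
            if behavior not in BEHAVIORS:
                raise ValueError(f"unknown behavior {behavior!r} in schedule")
            if duration <= 0:
                raise ValueError("segment durations must be positive")

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.segments))


@dataclass(frozen=True)
class GeneratorConfig:
    """Device-level generation settings.

    ``baseline_drift_sd`` is the per-sample scale of a Gaussian random walk
    emulating the slow baseline fluctuation the measurement apparatus was
    designed to minimize; ``noise_sd`` is white measurement noise.
    """

    sampling_interval: float = SAMPLING_INTERVAL
    baseline_level: float = 10.0
    baseline_drift_sd: float = 0.002
    noise_sd: float = 0.05
    multi_compartment: bool = False
    compartment_lags: dict[str, float] = field(
        default_factory=lambda: {"reticulum": 0.0, "cranial": 3.0,
                                 "dorsal": 8.0, "ventral": 14.0}
    )

    def __post_init__(self) -> None:
        if abs(self.sampling_interval - SAMPLING_INTERVAL) > 1e-9:
            raise ValueError(f"sampling_interval is fixed at {SAMPLING_INTERVAL} s")
        if self.noise_sd < 0 or self.baseline_drift_sd < 0:
            raise ValueError("noise scales must be non-negative")
        if self.multi_compartment:
            lags = [self.compartment_lags[c] for c in COMPARTMENTS]
            if any(b < a for a, b in zip(lags, lags[1:])):
                raise ValueError(
                    "compartment_lags must be non-decreasing in A-wave order "
                    f"{COMPARTMENTS}"
                )
            if self.compartment_lags.get("reticulum", 0.0) != 0.0:
                raise ValueError("reticulum lag must be 0 (A-wave origin)")


@dataclass(frozen=True)
class TruthCycle:
    """Ground-truth record of one generated contraction cycle."""

    cycle_id: int
    start_s: float
    end_s: float
    apex_times: tuple[float, ...]
    n_peaks: int
    behavior: str


@dataclass
class SessionData:
    """One generated session: trace(s), labels and ground-truth cycles."""

    traces: dict[str, PressureTrace]
    labels: BehaviorLabels
    truth_cycles: list[TruthCycle]
    clean: np.ndarray  # noise-free cycle train (baseline-relative), for propagation
    config: GeneratorConfig

    @property
    def trace(self) -> PressureTrace:
        return self.traces["reticulum"]

    def truth_gaps(self) -> np.ndarray:
        """Peak-free gaps between consecutive same-behavior truth cycles.

        Gaps spanning a behavior-segment boundary are excluded: cycles are
        re-initialized at segment starts, so only within-segment pairs carry
        the configured interval distribution.
        """
        gaps = []
        for a, b in zip(self.truth_cycles, self.truth_cycles[1:]):
            if a.behavior == b.behavior:
                gaps.append(b.start_s - a.end_s)
        return np.asarray(gaps)


def default_interval_params(behavior: str) -> IntervalParams:
    """Reported inter-cycle interval mean/SD for a behavior."""
    if behavior not in _INTERVAL_TABLE:
        raise ValueError(f"unknown behavior {behavior!r}; expected one of {BEHAVIORS}")
    mean, sd = _INTERVAL_TABLE[behavior]
    return IntervalParams(behavior=behavior, mean_gap=mean, sd_gap=sd)


def default_template(behavior: str) -> ContractionTemplate:
    """Triphasic template for rumination, biphasic for everything else."""
    if behavior not in BEHAVIORS:
        raise ValueError(f"unknown behavior {behavior!r}")
    return ContractionTemplate(peaks_per_cycle=3 if behavior == "rumination" else 2)


def generate_cycle_waveform(
    template: ContractionTemplate, rng: np.random.Generator
) -> np.ndarray:
    """One cycle's pressure segment on the 0.5 s grid, baseline-relative.

    The segment contains exactly ``peaks_per_cycle`` local maxima (Gaussian
    bumps with jittered amplitudes), rising from and returning to baseline.
    """
    dt = SAMPLING_INTERVAL
    n = int(round(template.duration / dt)) + 1
    t = dt * np.arange(n)
    sigma = template.peak_width * _FWHM_TO_SIGMA
    out = np.zeros(n)
    for k in range(template.peaks_per_cycle):
        apex = template.pad + k * template.intra_cycle_peak_spacing
        amp = template.peak_amplitude * (
            1.0 + template.amplitude_jitter * rng.uniform(-1.0, 1.0)
        )
        out += amp * np.exp(-0.5 * ((t - apex) / sigma) ** 2)
    return out


def generate_session(
    schedule: BehaviorSchedule,
    config: GeneratorConfig | None = None,
    templates: dict[str, ContractionTemplate] | None = None,
    intervals: dict[str, IntervalParams] | None = None,
    seed: int | np.random.Generator = 0,
) -> SessionData:
    """Generate one labeled session following a behavior schedule.

    Within each behavior segment, cycles are laid down left to right with
    peak-free gaps drawn from the behavior's truncated Normal interval
    distribution; a cycle that would straddle the segment end is dropped.
    The first cycle of a segment starts after one gap draw, as if a cycle
    had just ended at the boundary.  Identical seeds give identical output.
    """
    config = config or GeneratorConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = config.sampling_interval
    behaviors_used = {b for b, _ in schedule.segments}
    templates = dict(templates or {})
    intervals = dict(intervals or {})
    for b in behaviors_used:
        templates.setdefault(b, default_template(b))
        intervals.setdefault(b, default_interval_params(b))

    n_total = int(round(schedule.total_duration / dt))
    clean = np.zeros(n_total)
    labels = np.empty(n_total, dtype=object)
    truth: list[TruthCycle] = []

    seg_start = 0.0
    for behavior, duration in schedule.segments:
        seg_end = seg_start + duration
        i0 = int(round(seg_start / dt))
        i1 = int(round(seg_end / dt))
        labels[i0:i1] = behavior
        tpl = templates[behavior]
        par = intervals[behavior]
        pos = seg_start + float(par.draw(rng))
        while True:
            idx = int(round(pos / dt))
            start = idx * dt
            end = start + tpl.duration
            if end >= seg_end:  # a cycle may not straddle the boundary
                break
            wave = generate_cycle_waveform(tpl, rng)
            clean[idx : idx + wave.size] += wave
            apexes = tuple(start + tpl.pad + k * tpl.intra_cycle_peak_spacing
                           for k in range(tpl.peaks_per_cycle))
            truth.append(TruthCycle(
                cycle_id=len(truth), start_s=start, end_s=end,
                apex_times=apexes, n_peaks=tpl.peaks_per_cycle, behavior=behavior,
            ))
            pos = end + float(par.draw(rng))
        seg_start = seg_end

    drift = np.cumsum(rng.normal(0.0, config.baseline_drift_sd, n_total))
    noise = rng.normal(0.0, config.noise_sd, n_total)
    values = config.baseline_level + drift + clean + noise
    trace = PressureTrace(values, cow_id=schedule.cow_id, compartment="reticulum")
    label_obj = BehaviorLabels(labels, cow_id=schedule.cow_id)
    return SessionData(
        traces={"reticulum": trace}, labels=label_obj, truth_cycles=truth,
        clean=clean, config=config,
    )


def generate_multicompartment(
    session: SessionData,
    config: GeneratorConfig,
    seed: int | np.random.Generator = 0,
) -> SessionData:
    """Propagate the reticular cycle train over the four compartments.

    Each non-reticulum trace is the reticulum's noise-free cycle train
    delayed by the compartment lag, with its own independent baseline drift
    and measurement noise, emulating the cranio-caudal A-wave propagation
    (reticulum -> cranial -> dorsal -> ventral).
    """
    if not config.multi_compartment:
        raise ValueError("config.multi_compartment must be enabled")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = config.sampling_interval
    n = session.clean.size
    traces: dict[str, PressureTrace] = {"reticulum": session.trace}
    for comp in COMPARTMENTS[1:]:
        lag = config.compartment_lags[comp]
        shift = int(round(lag / dt))
        train = np.zeros(n)
        train[shift:] = session.clean[: n - shift] if shift else session.clean
        drift = np.cumsum(rng.normal(0.0, config.baseline_drift_sd, n))
        noise = rng.normal(0.0, config.noise_sd, n)
        traces[comp] = PressureTrace(
            config.baseline_level + drift + train + noise,
            cow_id=session.trace.cow_id, compartment=comp,
        )
    return SessionData(
        traces=traces, labels=session.labels, truth_cycles=session.truth_cycles,
        clean=session.clean, config=config,
    )


def write_truth_cycles(truth: list[TruthCycle], path) -> None:
    """Sidecar CSV of ground-truth cycles (cycle_id, start_s, end_s, n_peaks, behavior)."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "cycle_id": c.cycle_id,
                "start_s": c.start_s,
                "end_s": c.end_s,
                "n_peaks": c.n_peaks,
                "behavior": c.behavior,
            }
            for c in truth
        ],
        columns=["cycle_id", "start_s", "end_s", "n_peaks", "behavior"],
    ).to_csv(path, index=False)


def write_session_with_truth(session: SessionData, session_path, truth_path) -> None:
    """Write the session CSV plus its ground-truth cycle sidecar."""
    write_session(session.traces, session.labels, session_path)
    write_truth_cycles(session.truth_cycles, truth_path)
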