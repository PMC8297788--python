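import numpy as np
import pytest

from rumipress import (
    BehaviorSchedule,
    classify_rumination,
    cycle_window_features,
    detect_peaks,
    filter_cycles,
    generate_session,
    group_cycles,
    intercycle_intervals,
    normalize_trace,
)
from rumipress.peak_detection import ContractionCycle, Peak, PeakConfig, smooth

from conftest import gaussian_bump_trace

RULE_ONLY = PeakConfig(smoothing_window=0.0)  # bare rise/fall rule


def brute_force_apexes(x, config):
    """Exhaustive application of the rise/fall threshold rule.

    Scans every (rise, fall) index pair around every sample; qualifying
    samples are grouped and reduced to apices exactly as the rule states.
    Independent of the vectorized implementation.
    """
    xs = smooth(np.asarray(x, dtype=float), config)
    n = len(xs)
    k = int(round(config.rise_timespan / 0.5))
    thr = config.rise_threshold
    qual = []
    for m in range(n):
        rise = any(xs[m] - xs[i] >= thr for i in range(max(0, m - k), m + 1))
        fall = any(xs[m] - xs[j] >= thr for j in range(m, min(n - 1, m + k) + 1))
        if rise and fall:
            qual.append(m)
    merge = max(1, int(round(config.apex_merge_span / 0.5)))
    groups = []
    for m in qual:
        if groups and m - groups[-1][-1] <= merge:
            groups[-1].append(m)
        else:
            groups.append([m])
    apexes = []
    for g in groups:
        seg = list(xs[g[0] : g[-1] + 1])
        apexes.append(g[0] + seg.index(max(seg)))
    return apexes


def make_peak(apex, value=1.0, half_width=2.0):
    return Peak(onset_time=apex - half_width, apex_time=apex,
                offset_time=apex + half_width, apex_value=value)


def test_triangle_gives_one_peak_at_apex():
    # rises 1.0 over 2 s then falls symmetrically; threshold 0.8 within 3 s
    x = np.array([0.0, 0.25, 0.5, 0.75, 1.0, 0.75, 0.5, 0.25, 0.0, 0.0])
    peaks = detect_peaks(x, RULE_ONLY)
    assert len(peaks) == 1
    assert peaks[0].apex_time == 2.0  # sample index 4
    assert peaks[0].apex_value == 1.0
    assert peaks[0].onset_time <= 2.0 <= peaks[0].offset_time


def test_flat_and_subthreshold_traces_give_no_peaks():
    assert detect_peaks(np.zeros(100), RULE_ONLY) == []
    bump = gaussian_bump_trace([25.0], [0.5], 50.0)  # height 0.5 < 0.8
    assert detect_peaks(bump, RULE_ONLY) == []


def test_slow_rise_fails_timespan():
    # rises 1.0 over 10 s: surpasses the threshold but not within 3 s
    x = np.concatenate([np.linspace(0, 1, 21), np.linspace(1, 0, 21)])
    assert detect_peaks(x, PeakConfig(smoothing_window=0.0,
                                      rise_timespan=3.0)) == []
    # widening the timespan recovers the peak
    assert len(detect_peaks(x, PeakConfig(smoothing_window=0.0,
                                          rise_timespan=12.0))) == 1


@pytest.mark.parametrize("config", [RULE_ONLY, PeakConfig()],
                         ids=["bare-rule", "smoothed"])
def test_detector_matches_bruteforce_on_short_traces(config, rum_session,
                                                     eat_session):
    fixtures = [
        np.zeros(50),
        np.array([0.0, 0.25, 0.5, 0.75, 1.0, 0.75, 0.5, 0.25, 0.0, 0.0]),
        gaussian_bump_trace([20, 28, 36, 90, 98, 106], [3, 3.2, 2.8] * 2, 150.0),
        np.random.default_rng(0).normal(0, 0.6, 500),
        np.random.default_rng(1).normal(0, 1.2, 500),
        normalize_trace(rum_session.trace).values[:500],
        normalize_trace(eat_session.trace).values[1000:1500],
    ]
    for x in fixtures:
        got = [int(round(p.apex_time / 0.5)) for p in detect_peaks(x, config)]
        assert got == brute_force_apexes(x, config)


def test_threshold_monotonicity(rum_session):
    """Raising the rise threshold never increases the peak count."""
    x = normalize_trace(rum_session.trace).values
    counts = [
        len(detect_peaks(x, PeakConfig(rise_threshold=thr)))
        for thr in (0.4, 0.6, 0.8, 1.0, 1.5, 2.0, 3.0)
    ]
    assert counts == sorted(counts, reverse=True)


def test_group_cycles_by_apex_gap():
    peaks = [make_peak(t) for t in (10.0, 14.0, 18.0, 60.0, 64.0, 68.0)]
    cycles = group_cycles(peaks, PeakConfig(max_intra_cycle_gap=12.0))
    assert [c.n_peaks for c in cycles] == [3, 3]
    assert cycles[0].start_time == 8.0 and cycles[0].end_time == 20.0

    assert group_cycles([], PeakConfig()) == []
    single = group_cycles([make_peak(5.0)], PeakConfig())
    assert len(single) == 1 and single[0].n_peaks == 1


def test_peak_conservation(rum_session):
    x = normalize_trace(rum_session.trace).values
    peaks = detect_peaks(x)
    cycles = group_cycles(peaks)
    assert sum(c.n_peaks for c in cycles) == len(peaks)
    # every peak belongs to exactly one cycle
    assert sorted(p.apex_time for c in cycles for p in c.peaks) == [
        p.apex_time for p in peaks
    ]


def test_intercycle_intervals():
    def cycle(start, end):
        return ContractionCycle((make_peak(start + 2.0, half_width=2.0),
                                 make_peak(end - 2.0, half_width=2.0)))

    cycles = [cycle(20.0, 60.0), cycle(70.0, 110.0)]
    assert intercycle_intervals(cycles) == [10.0]
    assert intercycle_intervals(cycles[:1]) == []
    evenly = [cycle(0.0, 20.0), cycle(50.0, 70.0), cycle(100.0, 120.0)]
    assert intercycle_intervals(evenly) == [30.0, 30.0]


def test_filter_cycles_drops_singletons_and_long_runs():
    cycles = [
        ContractionCycle(tuple(make_peak(10.0 + 4 * i) for i in range(n)))
        for n in (1, 2, 3, 4, 5)
    ]
    kept = filter_cycles(cycles, PeakConfig(min_cycle_peaks=2, max_cycle_peaks=4))
    assert [c.n_peaks for c in kept] == [2, 3, 4]


def test_cycle_window_features_fixture():
    x = gaussian_bump_trace([50.0], [1.4], 200.0)
    cfg = RULE_ONLY  # no smoothing, so the apex value is the drawn 1.4
    cycles = group_cycles(detect_peaks(x, cfg), cfg)
    feats = cycle_window_features(x, cycles, cfg)
    assert len(feats) == len(x)
    # early windows see no peak: baseline = window median, peak fields absent
    row = feats.iloc[60]  # t = 30 s, apex at 50 s not yet seen
    assert np.isnan(row["highest_peak"]) and np.isnan(row["peak_value"])
    assert row["baseline"] == pytest.approx(0.0, abs=1e-6)
    # a window containing the apex reports it
    row = feats.iloc[150]  # t = 75 s
    assert row["highest_peak"] == pytest.approx(50.0, abs=0.5)
    assert row["peak_value"] == pytest.approx(1.4, rel=0.1)
    assert row["peak_value"] >= row["baseline"]


def test_cycle_window_interval_matches_intercycle_intervals(rum_session):
    norm = normalize_trace(rum_session.trace)
    cfg = PeakConfig()
    cycles = filter_cycles(group_cycles(detect_peaks(norm, cfg), cfg), cfg)
    gaps = intercycle_intervals(cycles)
    feats = cycle_window_features(norm.values, cycles, cfg)
    # at each cycle's start (a gap just closed), the reported interval is that gap
    for gap, closing in zip(gaps, cycles[1:]):
        i = int(round(closing.start_time / 0.5)) + 1
        assert feats["contraction_interval"].iloc[i] == pytest.approx(gap)


def test_classify_requires_75s():
    with pytest.raises(ValueError, match="75"):
        classify_rumination(np.zeros(100))


def test_rumination_session_flagged(rum_session):
    flags = classify_rumination(normalize_trace(rum_session.trace))
    assert flags.mean() >= 0.95


def test_eating_session_rarely_flagged(eat_session):
    flags = classify_rumination(normalize_trace(eat_session.trace))
    assert flags.mean() <= 0.05


def test_two_peak_exception():
    """A biphasic cycle whose span matches the triphasic median is ruminating."""
    tri_starts = [60.0 + 55.0 * i for i in range(6)]
    apexes, amps = [], []
    for s in tri_starts:
        apexes += [s, s + 4.0, s + 8.0]
        amps += [3.0, 3.0, 3.0]
    two_peak_start = tri_starts[-1] + 150.0  # isolated from triphasic coverage
    total = two_peak_start + 200.0

    # exception case: two peaks spaced like the outer peaks of a triphasic cycle
    x = gaussian_bump_trace(apexes + [two_peak_start, two_peak_start + 8.0],
                            amps + [3.0, 3.0], total)
    flags = classify_rumination(x)
    probe = int((two_peak_start + 60.0) / 0.5)
    assert flags[probe]

    # control: a narrow biphasic cycle (ordinary eating shape) is not flagged
    x2 = gaussian_bump_trace(apexes + [two_peak_start, two_peak_start + 4.0],
                             amps + [3.0, 3.0], total)
    flags2 = classify_rumination(x2)
    assert not flags2[probe]
    # while the triphasic region stays flagged in both
    tri_probe = int((tri_starts[3]) / 0.5)
    assert flags[tri_probe] and flags2[tri_probe]


def test_classification_idempotent_on_subtrace(rum_session):
    """Re-running on a sub-trace reproduces flags where windows are complete."""
    norm = normalize_trace(rum_session.trace).values
    full = classify_rumination(norm)
    a, b = 600, 3000
    sub = classify_rumination(norm[a:b])
    settle = 1200  # beyond window length + running-median initialization
    tail = 60  # a cycle cut at the sub-trace end is seen only by the full trace
    np.testing.assert_array_equal(sub[settle:-tail], full[a + settle : b - tail])
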