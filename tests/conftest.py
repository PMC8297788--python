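import numpy as np
import pytest

from rumipress import BehaviorSchedule, build_feature_matrix, generate_session


@pytest.fixture(scope="session")
def rum_session():
    """30 min of pure rumination with generator defaults."""
    return generate_session(
        BehaviorSchedule([("rumination", 1800.0)], cow_id="r1"), seed=42
    )


@pytest.fixture(scope="session")
def eat_session():
    """30 min of pure eating (biphasic cycles, 34 s gaps)."""
    return generate_session(
        BehaviorSchedule([("eating", 1800.0)], cow_id="e1"), seed=43
    )


@pytest.fixture(scope="session")
def mixed_session():
    """A short multi-segment session covering several behaviors."""
    schedule = BehaviorSchedule(
        [("other", 300.0), ("eating", 600.0), ("rumination", 900.0),
         ("sleeping", 300.0)],
        cow_id="m1",
    )
    return generate_session(schedule, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """Three cows with identical generating parameters, 30 min each."""
    schedule = [("eating", 540.0), ("rumination", 720.0), ("other", 360.0),
                ("sleeping", 180.0)]
    return [
        generate_session(BehaviorSchedule(list(schedule), cow_id=f"cow{i+1}"),
                         seed=100 + i)
        for i in range(3)
    ]


@pytest.fixture(scope="session")
def small_cohort_fm(small_cohort):
    return build_feature_matrix(small_cohort)


def gaussian_bump_trace(apex_times, amplitudes, total_s, width_fwhm=2.0):
    """Noise-free train of Gaussian bumps on the 0.5 s grid (baseline 0)."""
    t = np.arange(0.0, total_s, 0.5)
    sigma = width_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    x = np.zeros_like(t)
    for apex, amp in zip(apex_times, amplitudes):
        x += amp * np.exp(-0.5 * ((t - apex) / sigma) ** 2)
    return x
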