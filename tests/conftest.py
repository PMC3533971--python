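import numpy as np
import pytest
from hypothesis import settings

from accelcal.calibration import CalibrationSession, StageRecord, compute_mets

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

STAGE_SPEEDS = [2.0, 3.0, 4.0, 5.0, 6.0]


def make_linear_session(
    intercept: float,
    slope: float,
    counts=(200.0, 600.0, 1000.0, 1400.0, 1800.0),
    resting_vo2: float = 3.04,
    subject_id: str = "lin",
) -> CalibrationSession:
    """Session whose METs lie exactly on intercept + slope * counts."""
    stages = [
        StageRecord(speed=v, vo2=(intercept + slope * c) * resting_vo2, counts_per_min=c)
        for v, c in zip(STAGE_SPEEDS, counts)
    ]
    return compute_mets(CalibrationSession(subject_id, resting_vo2, stages))


@pytest.fixture
def rng():
    return np.random.default_rng(20121115)


# ---------------------------------------------------------------------------
# brute-force window-enumeration oracle for non-wear and bout rules
# ---------------------------------------------------------------------------

def oracle_greedy_windows(eligible, min_length: int, allowance: int):
    """Exhaustive-enumeration oracle for the greedy interval rules.

    Enumerates every window (s, e), keeps those that start and end on an
    eligible minute, contain at most ``allowance`` ineligible minutes, and
    span >= ``min_length``; then tiles greedily: smallest start first, the
    longest valid window at that start, resume after it.
    """
    elig = np.asarray(eligible, dtype=bool)
    n = elig.size
    bad = np.concatenate([[0], np.cumsum(~elig)])
    out = []
    s = 0
    while s < n:
        if not elig[s]:
            s += 1
            continue
        ends = np.arange(s + min_length, n + 1)
        ok = elig[ends - 1] & (bad[ends] - bad[s] <= allowance)
        if ok.any():
            e = int(ends[ok].max())
            out.append((s, e))
            s = e
        else:
            s += 1
    return out


def random_minute_stream(rng, n_minutes=300, p_zero=0.5, max_count=2000):
    """Zero-inflated random counts/min stream for detector stress tests."""
    zero = rng.random(n_minutes) < p_zero
    counts = rng.integers(1, max_count, size=n_minutes).astype(float)
    counts[zero] = 0.0
    return counts
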