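"""Free-living physical-activity scoring from minute-level count data.

The field pipeline reintegrates 10-s epochs to 60-s resolution, splits the
stream into calendar days, removes non-wear time, screens days for validity,
and tallies minutes of moderate-to-vigorous physical activity (MVPA) and
bouted MVPA under an arbitrary counts/min cut point.

Rules (all configurable, defaulting to the study convention):

* non-wear: maximal periods of >= 60 min with at most 2 minutes of non-zero
  counts; interruption minutes may have any magnitude;
* valid day: >= 600 minutes (10 h) of wear;
* valid measurement: >= 5 valid days;
* MVPA minute: worn and counts/min >= cut point;
* bout: a window of >= 10 min that starts and ends on an MVPA minute and
  contains at most 2 non-MVPA minutes in total (the "2-minute drop"
  allowance); bout minutes include the allowed drops.

Both interval detectors use a greedy left-to-right scan: open a candidate at
the first eligible minute, extend until a third interruption would be
included, trim trailing interruptions, emit if long enough, resume after the
emitted window. All intervals are 0-based half-open minute indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epoch_io import EpochSeries, reintegrate

__all__ = [
    "MinuteSeries",
    "DaySummary",
    "SubjectPA",
    "ScoringParams",
    "detect_non_wear",
    "classify_mvpa",
    "detect_bouts",
    "summarize_day",
    "summarize_subject",
]

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class ScoringParams:
    """Thresholds for non-wear, day validity, and bout detection (minutes)."""

    non_wear_window: int = 60
    non_wear_allowance: int = 2
    valid_day_wear: int = 600
    valid_days_required: int = 5
    bout_duration: int = 10
    bout_allowance: int = 2


@dataclass(frozen=True)
class MinuteSeries:
    """One calendar day of counts/min for a subject (<= 1440 minutes)."""

    subject_id: str
    day: pd.Timestamp
    counts_per_min: np.ndarray

    def __post_init__(self) -> None:
        cpm = np.asarray(self.counts_per_min, dtype=float)
        if cpm.ndim != 1 or cpm.size > MINUTES_PER_DAY:
            raise ValueError("counts_per_min must be 1-D with <= 1440 minutes")
        if cpm.size and np.any(cpm < 0):
            raise ValueError("counts/min must be non-negative")
        object.__setattr__(self, "counts_per_min", cpm)
        object.__setattr__(self, "day", pd.Timestamp(self.day).normalize())

    def __len__(self) -> int:
        return self.counts_per_min.size


@dataclass
class DaySummary:
    day: pd.Timestamp
    wear_minutes: int
    valid: bool
    mvpa_minutes: int
    bout_minutes: int
    n_bouts: int


@dataclass
class SubjectPA:
    """Per-subject physical-activity outcomes averaged over valid days."""

    subject_id: str
    n_valid_days: int
    valid_measurement: bool
    mvpa_per_day: float  # NaN when no valid days
    bouts_per_day: float
    total_pa: float  # counts/min over wear time of valid days
    days: list[DaySummary]


def _greedy_intervals(
    eligible: np.ndarray, min_length: int, allowance: int
) -> list[tuple[int, int]]:
    """Greedy maximal windows over a boolean eligibility mask.

    A window must start and end on an eligible minute, contain at most
    ``allowance`` ineligible minutes in total, and span >= ``min_length``
    minutes. Scan left to right: open at the first unconsumed eligible
    minute, extend until one more ineligible minute would exceed the
    allowance, trim trailing ineligible minutes, emit if long enough, then
    resume after the emitted window.
    """
    n = eligible.size
    ineligible_pos = np.flatnonzero(~eligible)
    out: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        # furthest end: window may contain `allowance` ineligible minutes,
        # so it stops just before the (allowance+1)-th one at or after i
        k = np.searchsorted(ineligible_pos, i)
        if k + allowance < ineligible_pos.size:
            end = int(ineligible_pos[k + allowance])
        else:
            end = n
        # trim trailing ineligible minutes so the window ends on an eligible one
        while end > i and not eligible[end - 1]:
            end -= 1
        if end - i >= min_length:
            out.append((i, end))
            i = end
        else:
            i += 1
    return out


def detect_non_wear(day: MinuteSeries, params: ScoringParams = ScoringParams()) -> list[tuple[int, int]]:
    """Non-wear intervals (half-open minute indices) for one day.

    Non-wear is >= 60 consecutive minutes of zero counts, allowing at most 2
    interruption minutes of any non-zero magnitude inside the period.
    Returned intervals are disjoint and in increasing order.
    """
    zero = day.counts_per_min == 0
    return _greedy_intervals(zero, params.non_wear_window, params.non_wear_allowance)


def wear_mask(day: MinuteSeries, params: ScoringParams = ScoringParams()) -> np.ndarray:
    mask = np.ones(len(day), dtype=bool)
    for s, e in detect_non_wear(day, params):
        mask[s:e] = False
    return mask


def classify_mvpa(day: MinuteSeries, wear: np.ndarray, cut_point: float) -> np.ndarray:
    """Boolean MVPA mask: worn and counts/min >= cut point.

    The boundary is inclusive: the cut point itself was derived by solving the
    calibration regression at exactly 3 METs, so a minute at the cut point
    attains the target intensity.
    """
    if cut_point <= 0:
        raise ValueError(f"cut point must be positive, got {cut_point}")
    if len(wear) != len(day):
        raise ValueError("wear mask length mismatch")
    return wear & (day.counts_per_min >= cut_point)


def detect_bouts(
    mvpa: np.ndarray, wear: np.ndarray, params: ScoringParams = ScoringParams()
) -> list[tuple[int, int]]:
    """Bouts of MVPA: greedy windows >= 10 min with <= 2 drop minutes.

    Drop minutes are any non-MVPA minutes (including non-wear, which cannot be
    bridged beyond the same 2-minute allowance). Bout length includes the
    allowed drops. Returns half-open (start, end) minute intervals.
    """
    if len(mvpa) != len(wear):
        raise ValueError("mask length mismatch")
    return _greedy_intervals(np.asarray(mvpa, dtype=bool), params.bout_duration, params.bout_allowance)


def summarize_day(
    day: MinuteSeries, cut_point: float, params: ScoringParams = ScoringParams()
) -> DaySummary:
    wear = wear_mask(day, params)
    mvpa = classify_mvpa(day, wear, cut_point)
    bouts = detect_bouts(mvpa, wear, params)
    wear_minutes = int(wear.sum())
    return DaySummary(
        day=day.day,
        wear_minutes=wear_minutes,
        valid=wear_minutes >= params.valid_day_wear,
        mvpa_minutes=int(mvpa.sum()),
        bout_minutes=sum(e - s for s, e in bouts),
        n_bouts=len(bouts),
    )


def split_days(series: EpochSeries) -> list[MinuteSeries]:
    """Reintegrate to 60-s epochs and split into calendar-aligned days.

    Partial first/last days are kept; the 600-minute wear rule screens them
    like any other day.
    """
    minutes = reintegrate(series, 60)
    ts = minutes.timestamps()
    df = pd.DataFrame({"ts": ts, "cpm": minutes.counts.astype(float)})
    out = []
    for day, sub in df.groupby(df["ts"].dt.normalize(), sort=True):
        out.append(
            MinuteSeries(subject_id=series.subject_id, day=day, counts_per_min=sub["cpm"].to_numpy())
        )
    return out


def summarize_subject(
    series: EpochSeries, cut_point: float, params: ScoringParams = ScoringParams()
) -> SubjectPA:
    """Score a multi-day epoch stream into per-subject outcomes.

    MVPA and bout minutes are averaged over valid days only; ``total_pa`` is
    total counts over wear time of valid days divided by total wear minutes.
    With zero valid days the measurement is invalid and per-day outcomes are
    reported as NaN.
    """
    days = split_days(series)
    if not days:
        raise ValueError("series covers no days")
    summaries = [summarize_day(d, cut_point, params) for d in days]
    valid = [(d, s) for d, s in zip(days, summaries) if s.valid]
    n_valid = len(valid)
    if n_valid:
        mvpa_pd = float(np.mean([s.mvpa_minutes for _, s in valid]))
        bouts_pd = float(np.mean([s.bout_minutes for _, s in valid]))
        total_counts = 0.0
        total_wear = 0
        for d, s in valid:
            w = wear_mask(d, params)
            total_counts += float(d.counts_per_min[w].sum())
            total_wear += s.wear_minutes
        total_pa = total_counts / total_wear if total_wear else float("nan")
    else:
        mvpa_pd = bouts_pd = total_pa = float("nan")
    return SubjectPA(
        subject_id=series.subject_id,
        n_valid_days=n_valid,
        valid_measurement=n_valid >= params.valid_days_required,
        mvpa_per_day=mvpa_pd,
        bouts_per_day=bouts_pd,
        total_pa=total_pa,
        days=summaries,
    )


def days_to_frame(subject: SubjectPA) -> pd.DataFrame:
    """Per-day tidy table (subject_id, day, wear, valid, mvpa, bouts)."""
    return pd.DataFrame(
        {
            "subject_id": subject.subject_id,
            "day": [s.day.date() for s in subject.days],
            "wear_minutes": [s.wear_minutes for s in subject.days],
            "valid": [s.valid for s in subject.days],
            "mvpa_minutes": [s.mvpa_minutes for s in subject.days],
            "bout_minutes": [s.bout_minutes for s in subject.days],
            "n_bouts": [s.n_bouts for s in subject.days],
        }
    )
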