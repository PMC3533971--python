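"""Synthetic calibration cohorts and free-living count streams with known truth.

The generators emulate the study population the pipeline was designed for —
severely obese adults walking slowly — with cohort statistics matching the
published sample: resting VO2 ~ 3.04 (0.40) ml/kg/min, individual cut points
(ICPs) ~ 1151 (685) counts/min truncated at the 100-count floor, BMI ~ 39.8
(5.7) kg/m2, and walking speeds at 3 METs spread between roughly 1 and
4 km/h.

Each subject is built backwards from a drawn true ICP: given the subject's
counts-per-speed slope k (counts/min per km/h above a baseline offset), the
speed at 3 METs is v3 = v0 + ICP/k, and the work economy (VO2 at 3 km/h) is
then the value that puts 3 x resting VO2 exactly at v3 on a linear VO2-speed
profile. ICP heterogeneity therefore arises jointly from resting VO2, work
economy and count-slope variation, reproducing the qualitative explanatory
structure of the cohort (higher resting VO2 and lower work economy push the
cut point up) without hard-coding any target partial correlation. Noiseless
scenarios are exactly invertible: the calibration fit recovers the drawn
ICPs to machine precision.

Free-living streams are planned at minute resolution (background light
activity, planted non-wear blocks of true zeros, and planted MVPA segments)
and then disaggregated to 10-s epochs conserving minute totals, so the truth
tables are exact at the analysis resolution. Planted MVPA intensities sit at
>= 2x the largest candidate cut point and background stays below 60% of the
smallest, so minute classifications never depend on noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationSession, StageRecord
from .epoch_io import EpochSeries

__all__ = [
    "CohortScenario",
    "FreeLivingScenario",
    "generate_calibration_cohort",
    "generate_group_model_cohort",
    "generate_two_hip_pair",
    "generate_freeliving",
]

STAGE_SPEEDS = (2.0, 3.0, 4.0, 5.0, 6.0)


class ScenarioError(ValueError):
    """Infeasible or inconsistent scenario parameters."""


@dataclass(frozen=True)
class CohortScenario:
    """Parameters of a synthetic calibration cohort.

    Distributional defaults follow the published cohort: resting VO2 mean/SD
    in ml/kg/min, ICP mean/SD in counts/min truncated at the 100-count floor,
    BMI in kg/m2. ``count_slope_*`` parameterize counts/min per km/h above
    the ``speed_offset``; ``vo2_speed_slope`` is the ml/kg/min cost of each
    additional km/h of walking speed. ``hip_noise_cv`` is the multiplicative
    between-hip perturbation of the count slope (same device-placement error
    for every stage of one hip), chosen so the implied between-hip cut-point
    SEM, hip_noise_cv * sqrt(E[ICP^2]), sits near the published 288
    counts/min. ``group_*`` are the truth values of the pooled mixed model
    used by the parameter-recovery generator.
    """

    n_subjects: int = 42
    resting_vo2_mean: float = 3.04
    resting_vo2_sd: float = 0.40
    icp_mean: float = 1151.0
    icp_sd: float = 685.0
    icp_min: float = 100.0
    bmi_mean: float = 39.8
    bmi_sd: float = 5.7
    bmi_icp_corr: float = 0.3
    count_slope_mean: float = 550.0
    count_slope_sd: float = 120.0
    count_slope_min: float = 200.0
    speed_offset: float = 0.8
    vo2_speed_slope: float = 1.8
    vo2_noise_sd: float = 0.75
    count_noise_sd: float = 60.0
    hip_noise_cv: float = 0.215
    max_speed_at_target: float = 5.5
    group_beta0: float = 2.5276
    group_beta1: float = 0.000690
    group_sigma2_u: float = 0.04
    group_rho: float = 0.5
    group_sigma2_e: float = 0.02

    def __post_init__(self) -> None:
        for name in ("resting_vo2_sd", "icp_sd", "bmi_sd", "count_slope_sd",
                     "vo2_noise_sd", "count_noise_sd", "hip_noise_cv"):
            if getattr(self, name) < 0:
                raise ScenarioError(f"{name} must be >= 0")
        if self.n_subjects < 0:
            raise ScenarioError("n_subjects must be >= 0")
        if not -1 < self.bmi_icp_corr < 1:
            raise ScenarioError("bmi_icp_corr must be in (-1, 1)")

    def expected_hip_sem(self) -> float:
        """Analytic between-hip cut-point SEM implied by ``hip_noise_cv``.

        With multiplicative slope errors, each hip's noiseless ICP is
        ICP*(1+delta), so SD(left-right)/sqrt(2) = hip_noise_cv*sqrt(E[ICP^2])
        (ignoring truncation and stage noise).
        """
        second_moment = self.icp_mean**2 + self.icp_sd**2
        return self.hip_noise_cv * float(np.sqrt(second_moment))


def _truncated_normal(rng, mean, sd, low=-np.inf, high=np.inf, max_tries=1000):
    if sd == 0:
        if not (low <= mean <= high):
            raise ScenarioError(f"degenerate draw {mean} outside [{low}, {high}]")
        return float(mean)
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    raise ScenarioError(f"truncated normal ({mean}, {sd}) in [{low}, {high}] infeasible")


def _draw_subject_latents(s: CohortScenario, rng, max_tries: int = 50) -> dict:
    """Latent physiology for one subject, built backwards from a drawn ICP.

    Tail combinations (very low resting VO2 with a very high cut point) can
    imply a non-positive VO2 at 2 km/h; such draws are rejected and redrawn,
    with an error only if the scenario makes them the rule rather than the
    exception.
    """
    for _ in range(max_tries):
        lat = _try_draw_subject_latents(s, rng)
        if lat is not None:
            return lat
    raise ScenarioError("scenario infeasible: implied VO2 at 2 km/h non-positive")


def _try_draw_subject_latents(s: CohortScenario, rng) -> dict | None:
    z_b = rng.standard_normal()
    bmi = s.bmi_mean + s.bmi_sd * z_b
    for _ in range(1000):
        z_i = s.bmi_icp_corr * z_b + np.sqrt(1 - s.bmi_icp_corr**2) * rng.standard_normal()
        icp = s.icp_mean + s.icp_sd * z_i
        if icp >= s.icp_min:
            break
    else:
        raise ScenarioError("ICP truncation exhausted")
    rvo2 = _truncated_normal(rng, s.resting_vo2_mean, s.resting_vo2_sd, low=1.5)
    # count slope constrained so the speed at target stays on a walkable range
    k_low = max(s.count_slope_min, icp / (s.max_speed_at_target - s.speed_offset))
    k = _truncated_normal(rng, s.count_slope_mean, s.count_slope_sd, low=k_low)
    v3 = s.speed_offset + icp / k
    work_economy = 3.0 * rvo2 - s.vo2_speed_slope * (v3 - 3.0)  # VO2 at 3 km/h
    if work_economy - s.vo2_speed_slope * 1.0 <= 0.2:
        return None
    # true regression of MET on counts implied by the linear profiles
    true_b = s.vo2_speed_slope / (k * rvo2)
    true_a = 3.0 - true_b * icp
    return {
        "bmi": bmi,
        "resting_vo2": rvo2,
        "count_slope": k,
        "true_icp": icp,
        "true_speed_at_3met": v3,
        "work_economy": work_economy,
        "true_a": true_a,
        "true_b": true_b,
    }


def _stages_from_latents(s: CohortScenario, lat: dict, rng, count_noise_sd=None) -> list[StageRecord]:
    if count_noise_sd is None:
        count_noise_sd = s.count_noise_sd
    stages = []
    for v in STAGE_SPEEDS:
        vo2_true = lat["work_economy"] + s.vo2_speed_slope * (v - 3.0)
        counts_true = lat["count_slope"] * (v - s.speed_offset)
        vo2 = max(vo2_true + (rng.normal(0, s.vo2_noise_sd) if s.vo2_noise_sd else 0.0), 0.2)
        counts = max(counts_true + (rng.normal(0, count_noise_sd) if count_noise_sd else 0.0), 0.0)
        stages.append(StageRecord(speed=v, vo2=vo2, counts_per_min=counts))
    return stages


def generate_calibration_cohort(
    s: CohortScenario, seed: int
) -> tuple[list[CalibrationSession], pd.DataFrame]:
    """Draw a calibration cohort and its hidden truth table.

    Returns one :class:`CalibrationSession` per subject (stage VO2 and
    counts/min at 2-6 km/h plus resting VO2, with measurement noise) and a
    truth DataFrame holding the drawn ICP, regression line, speed at 3 METs
    and covariates per subject.
    """
    rng = np.random.default_rng(seed)
    sessions, rows = [], []
    for i in range(s.n_subjects):
        sid = f"S{i + 1:03d}"
        lat = _draw_subject_latents(s, rng)
        sessions.append(
            CalibrationSession(
                subject_id=sid,
                resting_vo2=lat["resting_vo2"],
                stages=_stages_from_latents(s, lat, rng),
            )
        )
        rows.append({"subject_id": sid, **lat})
    truth = pd.DataFrame(
        rows,
        columns=["subject_id", "true_icp", "true_a", "true_b", "true_speed_at_3met",
                 "resting_vo2", "work_economy", "count_slope", "bmi"],
    )
    return sessions, truth


def generate_group_model_cohort(
    s: CohortScenario, seed: int, n_subjects: int | None = None
) -> tuple[list[CalibrationSession], dict]:
    """Cohort drawn exactly from the pooled mixed model, for recovery studies.

    MET_ij = beta0 + beta1*counts_ij + u_i + e_ij with u_i ~ N(0, sigma2_u)
    and within-subject AR(1)(rho) residuals of variance sigma2_e over stage
    order. Counts designs vary between subjects through the count slope.
    Stage VO2 is MET x resting VO2 so downstream MET computation reproduces
    the planted values exactly.
    """
    rng = np.random.default_rng(seed)
    n = s.n_subjects if n_subjects is None else n_subjects
    sessions = []
    for i in range(n):
        k = _truncated_normal(rng, s.count_slope_mean, s.count_slope_sd, low=s.count_slope_min)
        counts = k * (np.asarray(STAGE_SPEEDS) - s.speed_offset)
        u = rng.normal(0, np.sqrt(s.group_sigma2_u))
        e = np.empty(len(counts))
        sd_e = np.sqrt(s.group_sigma2_e)
        e[0] = rng.normal(0, sd_e)
        for j in range(1, len(counts)):
            e[j] = s.group_rho * e[j - 1] + rng.normal(0, sd_e * np.sqrt(1 - s.group_rho**2))
        mets = s.group_beta0 + s.group_beta1 * counts + u + e
        if np.any(mets <= 0):
            mets = np.maximum(mets, 0.05)
        rvo2 = _truncated_normal(rng, s.resting_vo2_mean, s.resting_vo2_sd, low=1.5)
        stages = [
            StageRecord(speed=v, vo2=float(m * rvo2), counts_per_min=float(c))
            for v, m, c in zip(STAGE_SPEEDS, mets, counts)
        ]
        sessions.append(CalibrationSession(subject_id=f"G{i + 1:03d}", resting_vo2=rvo2, stages=stages))
    truth = {
        "beta0": s.group_beta0,
        "beta1": s.group_beta1,
        "sigma2_u": s.group_sigma2_u,
        "rho": s.group_rho,
        "sigma2_e": s.group_sigma2_e,
    }
    return sessions, truth


def generate_two_hip_pair(
    s: CohortScenario, seed: int
) -> tuple[list[tuple[CalibrationSession, CalibrationSession]], pd.DataFrame]:
    """Paired right/left-hip calibration sessions for between-hip agreement.

    The metabolic measurement (VO2) is shared between hips; each hip sees the
    subject's latent count slope perturbed by an independent multiplicative
    error of CV ``hip_noise_cv`` plus independent stage count noise, so
    noiseless-limit hip ICPs are ICP*(1+delta_hip) and the expected
    between-hip SEM is analytic (:meth:`CohortScenario.expected_hip_sem`).
    """
    rng = np.random.default_rng(seed)
    pairs, rows = [], []
    for i in range(s.n_subjects):
        sid = f"S{i + 1:03d}"
        lat = _draw_subject_latents(s, rng)
        vo2_noise = rng.normal(0, s.vo2_noise_sd, size=len(STAGE_SPEEDS)) if s.vo2_noise_sd else np.zeros(len(STAGE_SPEEDS))
        hip_sessions = []
        for hip in ("right_hip", "left_hip"):
            delta = rng.normal(0, s.hip_noise_cv) if s.hip_noise_cv else 0.0
            k_hip = lat["count_slope"] * (1 + delta)
            stages = []
            for j, v in enumerate(STAGE_SPEEDS):
                vo2 = max(lat["work_economy"] + s.vo2_speed_slope * (v - 3.0) + vo2_noise[j], 0.2)
                c = k_hip * (v - s.speed_offset)
                if s.count_noise_sd:
                    c += rng.normal(0, s.count_noise_sd)
                stages.append(StageRecord(speed=v, vo2=vo2, counts_per_min=max(c, 0.0)))
            hip_sessions.append(
                CalibrationSession(subject_id=sid, resting_vo2=lat["resting_vo2"], stages=stages)
            )
        pairs.append((hip_sessions[0], hip_sessions[1]))
        rows.append({"subject_id": sid, **lat})
    return pairs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# free-living streams
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlannedBout:
    """A planted MVPA window: start minute (within-day), minute pattern.

    ``pattern`` is a boolean tuple, True = high-intensity minute, False = a
    drop minute at background intensity. A window qualifying as a bout must
    start/end on True and contain at most 2 False minutes.
    """

    start: int
    pattern: tuple[bool, ...]

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def high_minutes(self) -> int:
        return int(sum(self.pattern))

    @property
    def n_drops(self) -> int:
        return self.length - self.high_minutes


@dataclass(frozen=True)
class FreeLivingScenario:
    """Plan of a multi-day free-living measurement.

    Days are full calendar days; the device is worn between ``wear_start``
    and ``wear_end`` (minute-of-day) except for ``non_wear_per_day`` planted
    removal blocks of ``non_wear_minutes`` true zeros. Per day the plan
    plants ``bouts_per_day`` qualifying MVPA bouts (a fraction with the
    2-minute drop allowance exercised) and ``sporadic_runs_per_day`` short
    MVPA runs too brief to bout. ``candidate_cut_points`` are the cut points
    the truth table is tabulated for; planted high-intensity minutes are
    drawn at >= 2x their maximum and background below 60% of their minimum.
    """

    n_days: int = 7
    wear_start: int = 390  # 06:30
    wear_end: int = 1350  # 22:30
    non_wear_per_day: int = 1
    non_wear_minutes: int = 75
    bouts_per_day: int = 2
    bout_min_length: int = 10
    bout_max_length: int = 30
    drop_bout_fraction: float = 0.5
    sporadic_runs_per_day: int = 3
    sporadic_max_length: int = 5
    intermediate_runs_per_day: int = 0
    intermediate_max_length: int = 5
    intermediate_bout_fraction: float = 0.0
    candidate_cut_points: tuple[float, ...] = (685.0, 1151.0)
    subject_id: str = "F001"
    start_date: str = "2010-05-03"

    def __post_init__(self) -> None:
        if not 0 <= self.wear_start < self.wear_end <= 1440:
            raise ScenarioError("wear window must lie within the day")
        if self.non_wear_minutes < 60 and self.non_wear_per_day:
            raise ScenarioError("planted non-wear blocks must be >= 60 min to register")
        if self.bout_min_length < 10:
            raise ScenarioError("bouts must be >= 10 min to qualify")
        if not self.candidate_cut_points:
            raise ScenarioError("need at least one candidate cut point")

    @property
    def background_high(self) -> float:
        return 0.6 * min(self.candidate_cut_points)

    @property
    def mvpa_intensity(self) -> float:
        return 2.0 * max(self.candidate_cut_points)


def _plan_day(s: FreeLivingScenario, rng) -> tuple[list[tuple[int, int]], list[PlannedBout], list[tuple[int, int]]]:
    """Lay out non-wear blocks, bouts, and sporadic runs without conflicts.

    Activity segments are separated by >= 3 background minutes so no window
    spanning two segments can satisfy the 2-drop allowance, keeping the truth
    table a pure function of the plan.
    """
    occupied: list[tuple[int, int]] = []  # (start, end) with 3-min guard applied at placement

    def place(length: int, tries: int = 200) -> int:
        for _ in range(tries):
            start = int(rng.integers(s.wear_start + 1, s.wear_end - length - 1))
            if all(start >= e + 3 or start + length + 3 <= b for b, e in occupied):
                occupied.append((start, start + length))
                return start
        raise ScenarioError("could not place activity segment; day over-packed")

    non_wear = []
    for _ in range(s.non_wear_per_day):
        start = place(s.non_wear_minutes)
        non_wear.append((start, start + s.non_wear_minutes))

    bouts = []
    for b in range(s.bouts_per_day):
        length = int(rng.integers(s.bout_min_length, s.bout_max_length + 1))
        use_drops = rng.random() < s.drop_bout_fraction and length >= 12
        pattern = np.ones(length, dtype=bool)
        if use_drops:
            # two drop minutes strictly inside the window
            inner = rng.choice(np.arange(1, length - 1), size=2, replace=False)
            pattern[inner] = False
        start = place(length)
        bouts.append(PlannedBout(start=start, pattern=tuple(bool(x) for x in pattern)))

    sporadic = []
    for _ in range(s.sporadic_runs_per_day):
        length = int(rng.integers(1, s.sporadic_max_length + 1))
        start = place(length)
        sporadic.append((start, start + length))

    # short runs at intensities between the candidate cut points: MVPA under
    # the lower cut points only, never long enough to form a bout
    intermediate = []
    for _ in range(s.intermediate_runs_per_day):
        length = int(rng.integers(1, s.intermediate_max_length + 1))
        start = place(length)
        intermediate.append((start, start + length))
    return non_wear, bouts, sporadic, intermediate


def generate_freeliving(
    s: FreeLivingScenario, seed: int
) -> tuple[EpochSeries, pd.DataFrame]:
    """Generate a 10-s epoch stream plus its exact per-day truth table.

    The truth table has one row per (day, candidate cut point) with the wear,
    MVPA, bout minutes and bout count implied by the plan. Without
    intermediate runs the values are identical across candidate cut points
    (high-intensity minutes clear every cut, background clears none); planted
    intermediate runs add minutes that count as MVPA only under the cut
    points below their intensity.
    """
    rng = np.random.default_rng(seed)
    minute_days = []
    truth_rows = []
    cut_lo, cut_hi = min(s.candidate_cut_points), max(s.candidate_cut_points)
    start = pd.Timestamp(s.start_date)
    for d in range(s.n_days):
        non_wear, bouts, sporadic, intermediate = _plan_day(s, rng)
        cpm = np.zeros(1440)
        # background light activity over the wear window: strictly positive,
        # strictly below every candidate cut point (band shrinks for tiny cuts)
        bg_hi = s.background_high
        bg_lo = max(1.0, min(20.0, 0.5 * bg_hi))
        if bg_hi <= bg_lo:
            raise ScenarioError(f"candidate cut points too small for a background band "
                                f"({bg_lo:.1f} >= {bg_hi:.1f} counts/min)")
        n_wear_window = s.wear_end - s.wear_start
        cpm[s.wear_start:s.wear_end] = rng.uniform(bg_lo, bg_hi, size=n_wear_window)
        for b, e in non_wear:
            cpm[b:e] = 0.0
        high = s.mvpa_intensity
        lo_band = 1.05 * cut_lo
        hi_band = max(0.95 * cut_hi, lo_band + 1.0)  # cuts may nearly coincide
        # each bout carries one intensity value for all its active minutes, so
        # a bout either qualifies wholesale under a given cut or not at all
        bout_values = []
        for bout in bouts:
            if rng.random() < s.intermediate_bout_fraction and cut_hi > cut_lo:
                v = rng.uniform(lo_band, hi_band)
            else:
                v = high * rng.uniform(1.0, 1.3)
            for j, is_high in enumerate(bout.pattern):
                if is_high:
                    cpm[bout.start + j] = v
            bout_values.append(int(round(v)))
        for b, e in sporadic:
            cpm[b:e] = high * rng.uniform(1.0, 1.3, size=e - b)
        inter_counts = []
        for b, e in intermediate:
            vals = rng.uniform(lo_band, hi_band, size=e - b)
            cpm[b:e] = vals
            inter_counts.extend(np.round(vals).astype(int))
        minute_days.append(np.round(cpm).astype(np.int64))

        wear_minutes = n_wear_window - sum(e - b for b, e in non_wear)
        sporadic_minutes = sum(e - b for b, e in sporadic)
        for cut in s.candidate_cut_points:
            # planted minute values are integers after rounding; classify them
            # exactly as the scorer will (inclusive boundary)
            qualifying = [b for b, v in zip(bouts, bout_values) if v >= cut]
            inter_mvpa = sum(1 for v in inter_counts if v >= cut)
            truth_rows.append(
                {
                    "day": (start + pd.Timedelta(days=d)).date(),
                    "cut_point": cut,
                    "wear_minutes": wear_minutes,
                    "mvpa_minutes": sum(b.high_minutes for b in qualifying)
                    + sporadic_minutes + inter_mvpa,
                    "bout_minutes": sum(b.length for b in qualifying),
                    "n_bouts": len(qualifying),
                }
            )

    minutes = np.concatenate(minute_days)
    epochs = _disaggregate_minutes(minutes)
    series = EpochSeries(
        subject_id=s.subject_id,
        placement="right_hip",
        epoch_length=10,
        start_time=start,
        counts=epochs,
    )
    return series, pd.DataFrame(truth_rows)


def _disaggregate_minutes(minutes: np.ndarray) -> np.ndarray:
    """Spread minute counts over six 10-s epochs, conserving each minute total."""
    base, rem = np.divmod(minutes, 6)
    epochs = np.repeat(base, 6).reshape(-1, 6)
    # distribute the remainder over the first `rem` epochs of the minute
    offsets = np.arange(6)
    epochs += (offsets[None, :] < rem[:, None]).astype(np.int64)
    return epochs.reshape(-1)
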