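"""Individual and group accelerometer calibration against treadmill walking.

The calibration protocol measures each subject's resting oxygen uptake (VO2,
ml/kg/min) and steady-state VO2 plus mean accelerometer counts/min while
walking at 2, 3, 4, 5 and 6 km/h. Dividing walking VO2 by resting VO2 gives
individually adjusted MET values (or by the 3.5 ml/kg/min convention in
standard mode). An ordinary least-squares line of METs on counts/min per
subject, solved at 3 METs, yields that subject's individual cut point (ICP)
in counts/min; non-positive solutions are floored at 100 counts/min, since a
cut point of zero or below would classify all wear time as moderate-to-
vigorous activity.

The group cut point (GCP) comes from a linear mixed model pooled over
subjects,

    MET_ij = beta0 + beta1 * counts_ij + u_i + e_ij,

with a random intercept u_i ~ N(0, sigma2_u) per subject and within-subject
AR(1) residuals ordered by treadmill speed, fitted by restricted maximum
likelihood (REML). The GCP solves beta0 + beta1 * c = 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "StageRecord",
    "CalibrationSession",
    "SubjectCalibration",
    "GroupModel",
    "compute_mets",
    "fit_individual",
    "derive_icp",
    "speed_at_met",
    "fit_group_model",
    "STANDARD_MET_VO2",
    "ICP_FLOOR",
]

#: Conventional oxygen cost of 1 MET, ml/kg/min.
STANDARD_MET_VO2 = 3.5
#: Replacement cut point (counts/min) when the fitted line crosses 3 METs at <= 0.
ICP_FLOOR = 100.0


class SingularFitError(ValueError):
    """Regression design has no usable variation."""


class ConvergenceError(RuntimeError):
    """REML optimizer failed to converge; carries the best objective seen."""

    def __init__(self, message: str, best_objective: float):
        super().__init__(message)
        self.best_objective = best_objective


@dataclass
class StageRecord:
    """One treadmill stage: speed (km/h), steady-state VO2, mean counts/min."""

    speed: float
    vo2: float
    counts_per_min: float
    met: float | None = None

    def __post_init__(self) -> None:
        if self.vo2 <= 0:
            raise ValueError(f"stage VO2 must be positive, got {self.vo2}")
        if self.counts_per_min < 0:
            raise ValueError(f"counts/min must be >= 0, got {self.counts_per_min}")


@dataclass
class CalibrationSession:
    """A subject's resting VO2 and ordered treadmill stages."""

    subject_id: str
    resting_vo2: float
    stages: list[StageRecord]

    def __post_init__(self) -> None:
        if self.resting_vo2 <= 0:
            raise ValueError(f"resting VO2 must be positive, got {self.resting_vo2}")
        if len(self.stages) < 2:
            raise ValueError("a calibration session needs at least 2 stages")
        speeds = [s.speed for s in self.stages]
        if any(b <= a for a, b in zip(speeds, speeds[1:])):
            raise ValueError(f"stage speeds must be strictly increasing, got {speeds}")

    @property
    def mets(self) -> np.ndarray:
        if any(s.met is None for s in self.stages):
            raise ValueError("METs not computed; call compute_mets first")
        return np.array([s.met for s in self.stages])

    @property
    def counts(self) -> np.ndarray:
        return np.array([s.counts_per_min for s in self.stages])

    @property
    def speeds(self) -> np.ndarray:
        return np.array([s.speed for s in self.stages])


@dataclass
class SubjectCalibration:
    """Fitted per-subject counts->MET regression and derived cut point.

    ``intercept``/``slope`` are in METs and METs per (counts/min); ``see`` is
    the standard error of the estimate with denominator (n - p). ``icp`` is
    the counts/min at which the line crosses the target MET level, floored at
    100 when the raw crossing is <= 0 (``floor_applied``).
    """

    subject_id: str
    intercept: float
    slope: float
    pearson_r: float
    see: float
    icp: float | None = None
    floor_applied: bool = False
    model_order: str = "linear"
    quad_coef: float | None = None  # coefficient on counts^2 in quadratic mode


@dataclass
class GroupModel:
    """REML estimates of the pooled METs ~ counts/min mixed model."""

    beta0: float
    beta1: float
    sigma2_u: float
    rho: float
    sigma2_e: float
    ci_beta0: tuple[float, float]
    ci_beta1: tuple[float, float]
    gcp: float
    gcp_rounded: int
    n_subjects: int
    n_obs: int
    reml_loglik: float
    converged: bool = True


def compute_mets(session: CalibrationSession, mode: str = "individual") -> CalibrationSession:
    """Fill each stage's MET value.

    ``individual`` divides stage VO2 by the subject's own resting VO2 (the
    originally proposed 1-MET definition); ``standard`` divides by 3.5
    ml/kg/min.
    """
    if mode not in ("individual", "standard"):
        raise ValueError(f"mode must be 'individual' or 'standard', got {mode!r}")
    denom = session.resting_vo2 if mode == "individual" else STANDARD_MET_VO2
    stages = [replace(s, met=s.vo2 / denom) for s in session.stages]
    return replace(session, stages=stages)


def fit_individual(session: CalibrationSession, order: str = "linear") -> SubjectCalibration:
    """Least-squares fit of MET on counts/min for one subject.

    Linear mode needs >= 3 stages, quadratic >= 4 (one residual degree of
    freedom). Pearson r is the plain correlation between METs and counts (not
    a model R), reported as 0 with a warning when either variable is constant.
    SEE uses denominator (n - p), p = number of fitted coefficients.
    """
    if order not in ("linear", "quadratic"):
        raise ValueError(f"order must be 'linear' or 'quadratic', got {order!r}")
    y = session.mets
    c = session.counts
    p = 2 if order == "linear" else 3
    if len(y) < p + 1:
        raise ValueError(
            f"{order} fit needs >= {p + 1} stages for a residual degree of freedom, "
            f"got {len(y)}"
        )
    if np.ptp(c) == 0:
        raise SingularFitError(f"subject {session.subject_id}: zero variance in counts")

    cols = [np.ones_like(c), c] if order == "linear" else [np.ones_like(c), c, c**2]
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    see = float(np.sqrt(resid @ resid / (len(y) - p)))

    if np.ptp(y) == 0:
        warnings.warn(
            f"subject {session.subject_id}: constant MET across stages; "
            "Pearson r undefined, reported as 0",
            stacklevel=2,
        )
        r = 0.0
    else:
        r = float(np.corrcoef(c, y)[0, 1])

    return SubjectCalibration(
        subject_id=session.subject_id,
        intercept=float(coef[0]),
        slope=float(coef[1]),
        pearson_r=r,
        see=see,
        model_order=order,
        quad_coef=float(coef[2]) if order == "quadratic" else None,
    )


def derive_icp(cal: SubjectCalibration, target_met: float = 3.0) -> SubjectCalibration:
    """Solve the fitted regression at ``target_met`` for the individual cut point.

    Linear mode: icp = (target - a) / b. Quadratic mode: the smallest positive
    root of a + b*c + d*c^2 = target. A raw crossing <= 0 is replaced by the
    100 counts/min floor with ``floor_applied`` set; a boundary crossing at
    exactly 0 is floored too, since a zero cut point classifies all wear time
    as MVPA.
    """
    if cal.model_order == "quadratic" and cal.quad_coef not in (None, 0.0):
        roots = np.roots([cal.quad_coef, cal.slope, cal.intercept - target_met])
        real = sorted(r.real for r in roots if abs(r.imag) < 1e-9 and r.real > 0)
        raw = real[0] if real else -np.inf
    else:
        if cal.slope == 0:
            raise ZeroDivisionError(
                f"subject {cal.subject_id}: flat regression never crosses {target_met} METs"
            )
        if cal.slope < 0:
            warnings.warn(
                f"subject {cal.subject_id}: negative slope is physiologically "
                "implausible; cut point computed anyway",
                stacklevel=2,
            )
        raw = (target_met - cal.intercept) / cal.slope

    if raw <= 0:
        return replace(cal, icp=ICP_FLOOR, floor_applied=True)
    return replace(cal, icp=float(raw), floor_applied=False)


def speed_at_met(session: CalibrationSession, target_met: float = 3.0) -> float:
    """Walking speed (km/h) at which the subject reaches ``target_met``.

    Piecewise-linear interpolation of speed against the stage MET profile; if
    the target lies below the first stage's MET (subjects who exceed 3 METs
    already at 2 km/h), the line through the first two stages is extrapolated
    downward, clamped to > 0. For a non-monotone MET profile the first
    crossing is returned with a warning.
    """
    mets = session.mets
    speeds = session.speeds
    if np.any(np.diff(mets) <= 0):
        warnings.warn(
            f"subject {session.subject_id}: non-monotone MET profile; "
            "returning the first crossing",
            stacklevel=2,
        )
    if target_met < mets[0]:
        slope = (mets[1] - mets[0]) / (speeds[1] - speeds[0])
        if slope <= 0:
            # noisy profile: fall back to the least-squares MET~speed trend
            slope = float(np.polyfit(speeds, mets, 1)[0])
            if slope <= 0:
                raise ValueError("cannot extrapolate: MET profile does not increase with speed")
        v = speeds[0] + (target_met - mets[0]) / slope
        return max(float(v), 1e-6)
    for k in range(len(mets) - 1):
        lo, hi = mets[k], mets[k + 1]
        if min(lo, hi) <= target_met <= max(lo, hi) and lo != hi:
            frac = (target_met - lo) / (hi - lo)
            return float(speeds[k] + frac * (speeds[k + 1] - speeds[k]))
        if target_met == lo:
            return float(speeds[k])
    if target_met == mets[-1]:
        return float(speeds[-1])
    # above the last stage: extrapolate the final segment
    slope = (mets[-1] - mets[-2]) / (speeds[-1] - speeds[-2])
    if slope <= 0:
        slope = float(np.polyfit(speeds, mets, 1)[0])
        if slope <= 0:
            raise ValueError("cannot extrapolate: MET profile does not increase with speed")
    return float(speeds[-1] + (target_met - mets[-1]) / slope)


# ---------------------------------------------------------------------------
# REML mixed model
# ---------------------------------------------------------------------------

_SIGMA2_FLOOR = 1e-10


def _ar1_corr(n: int, rho: float) -> np.ndarray:
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _reml_pieces(theta: np.ndarray, groups: list[tuple[np.ndarray, np.ndarray]]):
    """Profiled-REML building blocks at variance parameters ``theta``.

    theta = (log sigma2_u, atanh rho, log sigma2_e). Returns the negative
    restricted log-likelihood plus the GLS fixed effects and their covariance.
    Each subject's covariance is V_i = sigma2_u * J + sigma2_e * R(rho), with
    R the AR(1) correlation over stage rank; V_i depends only on the group
    size, so one Cholesky per distinct size covers every subject.
    """
    sigma2_u = np.exp(theta[0])
    rho = np.tanh(theta[1])
    sigma2_e = max(np.exp(theta[2]), _SIGMA2_FLOOR)

    p = groups[0][0].shape[1]
    by_size: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
    for X, y in groups:
        by_size.setdefault(len(y), []).append((X, y))

    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    logdet_v = 0.0
    cached = []
    for n_i, members in by_size.items():
        V = sigma2_u * np.ones((n_i, n_i)) + sigma2_e * _ar1_corr(n_i, rho)
        try:
            Vinv = np.linalg.inv(V)
            sign, logdet = np.linalg.slogdet(V)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        if sign <= 0:
            return np.inf, None, None
        logdet_v += logdet * len(members)
        Xs = np.stack([X for X, _ in members])          # (m, n_i, p)
        ys = np.stack([y for _, y in members])          # (m, n_i)
        Vinv_X = np.einsum("ij,mjp->mip", Vinv, Xs)
        xtvx += np.einsum("mip,miq->pq", Xs, Vinv_X)
        xtvy += np.einsum("mip,mi->p", Vinv_X, ys)
        cached.append((Xs, ys, Vinv))

    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return np.inf, None, None
    beta = np.linalg.solve(xtvx, xtvy)
    quad = 0.0
    n_total = 0
    for Xs, ys, Vinv in cached:
        r = ys - Xs @ beta                               # (m, n_i)
        quad += float(np.einsum("mi,ij,mj->", r, Vinv, r))
        n_total += ys.size
    neg2_reml = logdet_v + logdet_xtvx + quad + (n_total - p) * np.log(2 * np.pi)
    return 0.5 * neg2_reml, beta, np.linalg.inv(xtvx)


def fit_group_model(
    sessions: list[CalibrationSession],
    target_met: float = 3.0,
) -> GroupModel:
    """Fit the pooled random-intercept/AR(1) mixed model and derive the GCP.

    REML is maximized numerically over (log sigma2_u, atanh rho, log sigma2_e)
    with the fixed effects profiled out, from three fixed starting points to
    guard against local optima. 95% intervals for the fixed effects are Wald
    intervals from the GLS covariance at the REML estimate. The group cut
    point is reported both unrounded and rounded to the nearest integer
    counts/min.
    """
    if len(sessions) < 2:
        raise ValueError("group model needs >= 2 subjects")
    groups = []
    for s in sessions:
        y = s.mets
        c = s.counts
        groups.append((np.column_stack([np.ones_like(c), c]), y))

    # scale counts to O(1) for optimizer conditioning; back-transform after
    scale = max(float(np.max([g[0][:, 1].max() for g in groups])), 1.0)
    scaled = [(np.column_stack([X[:, 0], X[:, 1] / scale]), y) for X, y in groups]

    starts = [
        np.array([np.log(0.05), np.arctanh(0.0), np.log(0.05)]),
        np.array([np.log(0.5), np.arctanh(0.5), np.log(0.01)]),
        np.array([np.log(0.005), np.arctanh(-0.3), np.log(0.2)]),
    ]
    best = None
    best_obj = np.inf
    for x0 in starts:
        res = optimize.minimize(
            lambda th: _reml_pieces(th, scaled)[0],
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        if res.fun < best_obj:
            best_obj = res.fun
            best = res
    if best is None or not np.isfinite(best_obj):
        raise ConvergenceError("REML optimization failed from all starts", best_obj)

    nll, beta_s, cov_s = _reml_pieces(best.x, scaled)
    sigma2_u = float(np.exp(best.x[0]))
    rho = float(np.tanh(best.x[1]))
    sigma2_e = float(max(np.exp(best.x[2]), _SIGMA2_FLOOR))
    if abs(rho) > 0.999:
        warnings.warn("AR(1) correlation estimate on the boundary (|rho| ~ 1)", stacklevel=2)

    beta0 = float(beta_s[0])
    beta1 = float(beta_s[1] / scale)
    se0 = float(np.sqrt(cov_s[0, 0]))
    se1 = float(np.sqrt(cov_s[1, 1]) / scale)
    z = stats.norm.ppf(0.975)
    if beta1 == 0:
        raise ZeroDivisionError("zero pooled slope: no finite group cut point")
    gcp = (target_met - beta0) / beta1

    return GroupModel(
        beta0=beta0,
        beta1=beta1,
        sigma2_u=sigma2_u,
        rho=rho,
        sigma2_e=sigma2_e,
        ci_beta0=(beta0 - z * se0, beta0 + z * se0),
        ci_beta1=(beta1 - z * se1, beta1 + z * se1),
        gcp=float(gcp),
        gcp_rounded=int(round(gcp)),
        n_subjects=len(sessions),
        n_obs=sum(len(g[1]) for g in groups),
        reml_loglik=-float(nll),
        converged=bool(best.success),
    )


def reml_negloglik(
    sessions: list[CalibrationSession],
    sigma2_u: float,
    rho: float,
    sigma2_e: float,
) -> float:
    """Negative restricted log-likelihood at given variance parameters.

    Exposed for diagnostics: lets callers compare the REML objective at the
    fitted estimate against e.g. simulation truth.
    """
    groups = []
    for s in sessions:
        c = s.counts
        groups.append((np.column_stack([np.ones_like(c), c]), s.mets))
    scale = max(float(np.max([g[0][:, 1].max() for g in groups])), 1.0)
    scaled = [(np.column_stack([X[:, 0], X[:, 1] / scale]), y) for X, y in groups]
    theta = np.array([np.log(max(sigma2_u, 1e-12)), np.arctanh(rho), np.log(max(sigma2_e, 1e-12))])
    return float(_reml_pieces(theta, scaled)[0])
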