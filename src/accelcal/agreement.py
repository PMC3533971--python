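"""Method-comparison and association statistics.

Implements the agreement toolkit used to compare cut points and the activity
outcomes they produce: Bland-Altman differences with the standard error of
measurement (SEM = SD of differences / sqrt(2)) and limits of agreement
(LoA = SEM * sqrt(2) * 1.96, i.e. 1.96 * SD of differences), a
between-method coefficient of variation, Spearman and Wilcoxon paired
comparisons, partial correlations from a multiple linear model, polynomial
(quadratic) association models, and the 2x2 guideline-reclassification table
with Cohen's kappa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PairedMeasures",
    "AgreementReport",
    "AssociationReport",
    "bland_altman",
    "cv_between_methods",
    "partial_correlations",
    "polynomial_association",
    "guideline_reclassification",
    "wilcoxon_signed_rank",
    "ReclassificationReport",
]


@dataclass(frozen=True)
class PairedMeasures:
    """Two same-unit measurements per subject (x = method A, y = method B)."""

    ids: tuple
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D and the same length")
        if len(x) != len(self.ids):
            raise ValueError("ids length mismatch")
        if len(x) < 3:
            raise ValueError("paired comparison needs n >= 3")
        if np.isnan(x).any() or np.isnan(y).any():
            raise ValueError("pairs must be complete (no NaN)")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @classmethod
    def from_arrays(cls, x, y, ids=None) -> "PairedMeasures":
        x = np.asarray(x, dtype=float)
        ids = tuple(ids) if ids is not None else tuple(range(len(x)))
        return cls(ids=ids, x=x, y=y)


@dataclass
class AgreementReport:
    n: int
    median_diff: float
    iqr_diff: float
    mean_diff: float
    sd_diff: float
    sem: float
    loa: float
    center: str
    limits: tuple[float, float]
    cv_percent: float
    spearman_rho: float
    spearman_p: float
    wilcoxon_stat: float
    wilcoxon_p: float


@dataclass
class AssociationReport:
    terms: list[str]
    coefficients: np.ndarray
    partial_r: dict[str, float]
    r_squared: float
    f_stat: float
    f_pvalue: float
    p_values: dict[str, float]


def bland_altman(p: PairedMeasures, center: str = "median") -> AgreementReport:
    """Bland-Altman agreement between two methods.

    Differences d = y - x; SD with the (n-1) denominator; SEM = SD/sqrt(2);
    LoA = SEM*sqrt(2)*1.96 (algebraically 1.96*SD). Limits are
    center(d) +/- LoA where the center is the median by default (the
    convention used when differences are reported as median with IQR), with
    the mean available.
    """
    if center not in ("median", "mean"):
        raise ValueError(f"center must be 'median' or 'mean', got {center!r}")
    d = p.y - p.x
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        warnings.warn("zero variance in differences; LoA = 0", stacklevel=2)
    sem = sd / np.sqrt(2)
    loa = sem * np.sqrt(2) * 1.96
    mid = float(np.median(d)) if center == "median" else float(np.mean(d))
    q1, q3 = np.percentile(d, [25, 75])
    try:
        cv = cv_between_methods(p)
    except ValueError:
        cv = float("nan")  # CV undefined for non-positive grand means
    rho, rho_p = stats.spearmanr(p.x, p.y)
    w_stat, w_p = wilcoxon_signed_rank(p)
    return AgreementReport(
        n=len(d),
        median_diff=float(np.median(d)),
        iqr_diff=float(q3 - q1),
        mean_diff=float(np.mean(d)),
        sd_diff=sd,
        sem=float(sem),
        loa=float(loa),
        center=center,
        limits=(mid - loa, mid + loa),
        cv_percent=cv,
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        wilcoxon_stat=w_stat,
        wilcoxon_p=w_p,
    )


def cv_between_methods(p: PairedMeasures, per_pair: bool = False) -> float:
    """Between-method coefficient of variation, percent.

    Default: SD of the paired differences over the grand mean of all 2n
    observations, x 100 — the typical-error-as-CV reading of "CV (SD/mean)".
    A constant shift between methods therefore contributes nothing. With
    ``per_pair=True``, the mean of per-pair CVs (SD of the two values over
    their mean) is returned instead.
    """
    grand_mean = float(np.mean(np.concatenate([p.x, p.y])))
    if grand_mean <= 0:
        raise ValueError("grand mean must be positive for a CV")
    if per_pair:
        pair_sd = np.abs(p.y - p.x) / np.sqrt(2)
        pair_mean = (p.x + p.y) / 2
        if np.any(pair_mean <= 0):
            raise ValueError("per-pair CV needs positive pair means")
        return float(np.mean(pair_sd / pair_mean) * 100)
    sd = float(np.std(p.y - p.x, ddof=1))
    return 100.0 * sd / grand_mean


def partial_correlations(outcome, predictors) -> AssociationReport:
    """Multiple linear model with effects reported as partial correlations.

    ``predictors`` is a DataFrame-like named matrix. The partial r for
    predictor j is t_j / sqrt(t_j^2 + df_resid), signed by the coefficient's
    t statistic.
    """
    import pandas as pd

    X = pd.DataFrame(predictors).astype(float)
    y = np.asarray(outcome, dtype=float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X.to_numpy()]))
    if rank < X.shape[1] + 1:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.max().idxmax()
        raise ValueError(f"rank-deficient design; check collinear column {worst!r}")
    model = sm.OLS(y, sm.add_constant(X)).fit()
    df_resid = model.df_resid
    partial = {
        name: float(t / np.sqrt(t**2 + df_resid))
        for name, t in model.tvalues.drop("const").items()
    }
    return AssociationReport(
        terms=list(X.columns),
        coefficients=model.params.to_numpy(),
        partial_r=partial,
        r_squared=float(model.rsquared),
        f_stat=float(model.fvalue),
        f_pvalue=float(model.f_pvalue),
        p_values={name: float(v) for name, v in model.pvalues.drop("const").items()},
    )


def polynomial_association(outcome, x, degree: int = 2) -> AssociationReport:
    """Polynomial (degree 1 or 2) least-squares association model."""
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if len(y) <= degree + 1:
        raise ValueError("need n > degree + 1")
    import pandas as pd

    cols = {"x": x} if degree == 1 else {"x": x, "x2": x**2}
    return partial_correlations(y, pd.DataFrame(cols))


def quadratic_vs_linear_f(outcome, x) -> tuple[float, float]:
    """Nested F-test comparing degree-2 against degree-1 fits.

    Returns (F, p) for the added quadratic term.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(outcome, dtype=float)
    X1 = sm.add_constant(x)
    X2 = sm.add_constant(np.column_stack([x, x**2]))
    m1 = sm.OLS(y, X1).fit()
    m2 = sm.OLS(y, X2).fit()
    res = m2.compare_f_test(m1)
    return float(res[0]), float(res[1])


@dataclass
class ReclassificationReport:
    table: np.ndarray  # rows: method A meets guideline (yes/no); cols: method B
    percent_agreement: float
    kappa: float  # NaN when undefined (degenerate margins)
    kappa_p: float
    threshold: float


def guideline_reclassification(
    bouts_a, bouts_b, threshold: float = 30.0
) -> ReclassificationReport:
    """Agreement on meeting the >= 30 min/day bouted-MVPA guideline.

    Classifies each subject under both methods, returns the 2x2 table,
    observed percent agreement, and Cohen's kappa with a normal-approximation
    p-value against kappa = 0. When either method puts all subjects in one
    class, kappa is undefined (NaN) but agreement is still reported.
    """
    a = np.asarray(bouts_a, dtype=float) >= threshold
    b = np.asarray(bouts_b, dtype=float) >= threshold
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need paired classifications with n >= 2")
    n = len(a)
    table = np.array(
        [
            [int(np.sum(a & b)), int(np.sum(a & ~b))],
            [int(np.sum(~a & b)), int(np.sum(~a & ~b))],
        ]
    )
    po = (table[0, 0] + table[1, 1]) / n
    pa_yes = table[0].sum() / n
    pb_yes = table[:, 0].sum() / n
    pe = pa_yes * pb_yes + (1 - pa_yes) * (1 - pb_yes)
    if pe == 1.0:
        warnings.warn("degenerate margins: kappa undefined", stacklevel=2)
        kappa = float("nan")
        p = float("nan")
    else:
        kappa = (po - pe) / (1 - pe)
        # large-sample SE of kappa under the null (Fleiss), normal approximation
        se0 = np.sqrt(
            (pe + pe**2 - (pa_yes * pb_yes * (pa_yes + pb_yes)
             + (1 - pa_yes) * (1 - pb_yes) * (2 - pa_yes - pb_yes)))
        ) / ((1 - pe) * np.sqrt(n))
        z = kappa / se0 if se0 > 0 else np.inf
        p = float(2 * stats.norm.sf(abs(z)))
    return ReclassificationReport(
        table=table,
        percent_agreement=100.0 * po,
        kappa=float(kappa),
        kappa_p=p,
        threshold=threshold,
    )


def bland_altman_plot(p: PairedMeasures, report: AgreementReport, path) -> None:
    """Difference vs pairwise-mean scatter with dashed 95% limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = p.y - p.x
    mean = (p.x + p.y) / 2
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.scatter(mean, d, s=22, color="black", zorder=3)
    mid = report.median_diff if report.center == "median" else report.mean_diff
    ax.axhline(mid, color="black", lw=1)
    for limit in report.limits:
        ax.axhline(limit, color="black", lw=1, ls="--")
    ax.set_xlabel("Mean of the two methods")
    ax.set_ylabel("Difference (y − x)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def wilcoxon_signed_rank(p: PairedMeasures | None = None, diffs=None) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test on non-zero differences.

    Exact null distribution (enumeration over sign patterns) when the number
    of non-zero differences is <= 25; normal approximation with continuity
    correction otherwise. All-zero differences give p = 1 with a warning.
    Returns (statistic, two-sided p).
    """
    d = np.asarray(diffs, dtype=float) if diffs is not None else p.y - p.x
    nonzero = d[d != 0]
    if nonzero.size == 0:
        warnings.warn("all differences zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    if nonzero.size < 5:
        warnings.warn(
            f"only {nonzero.size} non-zero differences; exact test has low power",
            stacklevel=2,
        )
    method = "exact" if nonzero.size <= 25 else "approx"
    res = stats.wilcoxon(
        nonzero, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return float(res.statistic), float(res.pvalue)
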