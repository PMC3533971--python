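import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from accelcal.agreement import (
    PairedMeasures,
    bland_altman,
    cv_between_methods,
    guideline_reclassification,
    partial_correlations,
    polynomial_association,
    quadratic_vs_linear_f,
    wilcoxon_signed_rank,
)


def pairs(x, y):
    return PairedMeasures.from_arrays(x, y)


class TestBlandAltman:
    def test_identical_methods_have_zero_limits(self):
        x = [10.0, 20.0, 30.0, 40.0]
        with pytest.warns(UserWarning, match="zero variance"):
            rep = bland_altman(pairs(x, x))
        assert rep.sem == 0.0
        assert rep.loa == 0.0
        assert rep.limits == (0.0, 0.0)

    def test_sem_is_sd_of_differences_over_sqrt2(self):
        x = np.array([0.0, 0.0, 0.0])
        y = np.array([-5.0, 0.0, 5.0])
        rep = bland_altman(pairs(x, y))
        assert rep.sd_diff == pytest.approx(5.0)
        assert rep.sem == pytest.approx(5.0 / np.sqrt(2))
        assert rep.loa == pytest.approx(1.96 * 5.0)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=30),
           st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=30))
    @settings(deadline=None, max_examples=40)
    def test_loa_identity_and_swap_symmetry(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n]), np.array(ys[:n])
        if np.std(y - x, ddof=1) == 0 or np.mean(np.concatenate([x, y])) <= 0:
            x = x + 100.0
            y = y + 101.0 + np.arange(n)  # force variance and a positive grand mean
        rep = bland_altman(pairs(x, y))
        assert rep.loa == pytest.approx(1.96 * rep.sd_diff)  # the two printed formulas agree
        swapped = bland_altman(pairs(y, x))
        assert swapped.median_diff == pytest.approx(-rep.median_diff)
        assert swapped.limits[0] == pytest.approx(-rep.limits[1])
        assert swapped.limits[1] == pytest.approx(-rep.limits[0])
        assert swapped.sem == pytest.approx(rep.sem)
        assert swapped.cv_percent == pytest.approx(rep.cv_percent, nan_ok=True)

    def test_plot_written_to_disk(self, rng, tmp_path):
        from accelcal.agreement import bland_altman_plot

        x = rng.uniform(500, 2500, size=15)
        y = x + rng.normal(scale=300, size=15)
        p = pairs(x, y)
        path = tmp_path / "ba.png"
        bland_altman_plot(p, bland_altman(p), path)
        assert path.stat().st_size > 0

    def test_mean_center_available(self):
        x = np.array([0.0, 0.0, 0.0, 0.0])
        y = np.array([1.0, 2.0, 3.0, 10.0])
        rep = bland_altman(pairs(x, y), center="mean")
        assert rep.limits[0] == pytest.approx(np.mean(y) - rep.loa)


class TestCv:
    def test_identical_methods_zero(self):
        assert cv_between_methods(pairs([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])) == 0.0

    def test_pure_bias_contributes_nothing(self):
        assert cv_between_methods(pairs([10.0] * 3, [20.0] * 3)) == 0.0

    def test_hand_computed_example(self):
        # d = (20, -20, 0), sd = 20; grand mean of all six = 80 -> 25%
        p = pairs([40.0, 80.0, 120.0], [60.0, 60.0, 120.0])
        assert cv_between_methods(p) == pytest.approx(100 * 20 / 80)

    def test_nonpositive_grand_mean_rejected(self):
        with pytest.raises(ValueError):
            cv_between_methods(pairs([-10.0, -20.0, -30.0], [-10.0, -21.0, -30.0]))


class TestPartialCorrelations:
    def test_single_predictor_equals_pearson(self, rng):
        x = rng.normal(size=40)
        y = 2.0 + 0.5 * x + rng.normal(size=40)
        rep = partial_correlations(y, pd.DataFrame({"x": x}))
        assert rep.partial_r["x"] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_matches_residual_on_residual_oracle(self, rng):
        """Partial r via t statistics equals the residual-correlation definition."""
        n = 60
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        y = 1.0 + 0.8 * X["a"] - 0.5 * X["b"] + rng.normal(size=n)
        rep = partial_correlations(y, X)
        for j in X.columns:
            others = X.drop(columns=j).to_numpy()
            Z = np.column_stack([np.ones(n), others])
            ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
            rx = X[j] - Z @ np.linalg.lstsq(Z, X[j], rcond=None)[0]
            assert rep.partial_r[j] == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-10)

    def test_orthogonal_predictor_near_zero(self, rng):
        n = 2000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = x1 + 0.5 * rng.normal(size=n)
        rep = partial_correlations(y, pd.DataFrame({"x1": x1, "x2": x2}))
        assert abs(rep.partial_r["x2"]) < 0.08

    def test_collinear_design_rejected(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            partial_correlations(rng.normal(size=30), X)


class TestPolynomialAssociation:
    def test_exact_quadratic_has_unit_r_squared(self, rng):
        x = rng.uniform(100, 2500, size=30)
        y = 120.0 - 0.1 * x + 2.5e-5 * x**2
        rep = polynomial_association(y, x, degree=2)
        assert rep.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_independent_outcome_near_zero_r_squared(self, rng):
        x = rng.uniform(0, 1, size=500)
        y = rng.normal(size=500)
        rep = polynomial_association(y, x, degree=2)
        assert rep.r_squared < 0.03

    def test_nested_f_detects_curvature(self, rng):
        x = rng.uniform(0, 10, size=80)
        y_curved = (x - 5) ** 2 + rng.normal(scale=0.5, size=80)
        f, p = quadratic_vs_linear_f(y_curved, x)
        assert p < 1e-6
        y_straight = 2 * x + rng.normal(scale=0.5, size=80)
        _, p2 = quadratic_vs_linear_f(y_straight, x)
        assert p2 > 0.01


class TestGuidelineReclassification:
    def test_identical_classifications(self):
        b = [40.0, 10.0, 50.0, 5.0, 31.0]
        rep = guideline_reclassification(b, b)
        assert rep.percent_agreement == 100.0
        assert rep.kappa == pytest.approx(1.0)

    def test_hand_worked_2x2_table(self):
        # both >= 30: 3; only A: 1; only B: 2; neither: 4  -> agreement 70%, kappa 0.40
        a = [40] * 3 + [40] * 1 + [10] * 2 + [10] * 4
        b = [40] * 3 + [10] * 1 + [40] * 2 + [10] * 4
        rep = guideline_reclassification(a, b)
        assert rep.table.tolist() == [[3, 1], [2, 4]]
        assert rep.percent_agreement == pytest.approx(70.0)
        po, pe = 0.7, 0.4 * 0.5 + 0.6 * 0.5
        assert rep.kappa == pytest.approx((po - pe) / (1 - pe))  # = 0.40
        assert rep.kappa == pytest.approx(0.40)

    def test_matches_sklearn_kappa(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.uniform(0, 60, size=100)
        b = a + rng.normal(scale=15, size=100)
        rep = guideline_reclassification(a, b)
        expected = cohen_kappa_score(a >= 30, b >= 30)
        assert rep.kappa == pytest.approx(expected, abs=1e-12)

    def test_independent_classifications_near_chance(self, rng):
        a = rng.uniform(0, 60, size=4000)
        b = rng.uniform(0, 60, size=4000)
        rep = guideline_reclassification(a, b)
        assert abs(rep.kappa) < 0.05

    def test_degenerate_margins_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            rep = guideline_reclassification([40.0, 50.0, 60.0], [45.0, 55.0, 65.0])
        assert np.isnan(rep.kappa)
        assert rep.percent_agreement == 100.0

    def test_kappa_invariant_to_label_swap(self, rng):
        a = rng.uniform(0, 60, size=50)
        b = a + rng.normal(scale=20, size=50)
        k_ab = guideline_reclassification(a, b).kappa
        k_ba = guideline_reclassification(b, a).kappa
        assert k_ab == pytest.approx(k_ba)


def exact_wilcoxon_p(diffs):
    """Brute-force two-sided p: enumerate all sign assignments of |d|.

    Two-sided by tail doubling (2 * min tail, capped at 1), the convention of
    the exact signed-rank test.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    n = len(d)
    stats_all = np.array(
        [np.array(signs) @ ranks for signs in itertools.product([0, 1], repeat=n)]
    )
    lower = np.mean(stats_all <= w_obs + 1e-12)
    upper = np.mean(stats_all >= w_obs - 1e-12)
    return min(1.0, 2 * min(lower, upper))


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        p = pairs([0.0] * 6, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        stat, pval = wilcoxon_signed_rank(p)
        assert pval == pytest.approx(2 / 64)

    def test_matches_enumeration_oracle(self, rng):
        # continuous draws: tie-free ranks, where the exact null is unambiguous
        for _ in range(5):
            d = rng.normal(scale=3, size=9)
            _, pval = wilcoxon_signed_rank(diffs=d)
            assert pval == pytest.approx(exact_wilcoxon_p(d), abs=1e-10)

    def test_symmetric_differences_not_significant(self):
        p = pairs([0.0] * 4, [1.0, -1.0, 2.0, -2.0])
        with pytest.warns(UserWarning, match="low power"):
            _, pval = wilcoxon_signed_rank(p)
        assert pval > 0.5

    def test_all_zero_differences(self):
        p = pairs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="all differences zero"):
            stat, pval = wilcoxon_signed_rank(p)
        assert pval == 1.0

    def test_large_n_uses_normal_approximation(self, rng):
        d = rng.normal(loc=0.5, size=60)
        _, pval = wilcoxon_signed_rank(diffs=d)
        assert 0.0 < pval < 1.0
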