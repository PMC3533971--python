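import numpy as np
import pytest
import statsmodels.api as sm

from accelcal.calibration import (
    CalibrationSession,
    SingularFitError,
    StageRecord,
    SubjectCalibration,
    compute_mets,
    derive_icp,
    fit_group_model,
    fit_individual,
    reml_negloglik,
    speed_at_met,
)
from accelcal.synthetic_data import CohortScenario, generate_group_model_cohort
from conftest import make_linear_session

# the published pooled model, used as a convenient noiseless truth
BETA0, BETA1 = 2.5276, 0.000690


class TestComputeMets:
    def test_individual_mode_is_ratio_to_resting(self):
        s = CalibrationSession("a", 3.04, [
            StageRecord(2.0, 9.12, 500.0), StageRecord(3.0, 3.04, 800.0),
        ])
        mets = compute_mets(s).mets
        assert mets[0] == pytest.approx(3.0)
        assert mets[1] == pytest.approx(1.0)  # resting VO2 defines 1 MET

    def test_standard_mode_divides_by_3_5(self):
        s = CalibrationSession("a", 3.04, [
            StageRecord(2.0, 10.5, 500.0), StageRecord(3.0, 14.0, 800.0),
        ])
        assert compute_mets(s, mode="standard").mets[0] == pytest.approx(3.0)

    def test_nonpositive_resting_vo2_rejected(self):
        with pytest.raises(ValueError):
            CalibrationSession("a", 0.0, [StageRecord(2.0, 9.0, 500.0),
                                          StageRecord(3.0, 10.0, 800.0)])


class TestSessionValidation:
    def test_speeds_must_strictly_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            CalibrationSession("a", 3.0, [StageRecord(3.0, 9.0, 500.0),
                                          StageRecord(2.0, 10.0, 800.0)])

    def test_needs_two_stages(self):
        with pytest.raises(ValueError, match="2 stages"):
            CalibrationSession("a", 3.0, [StageRecord(2.0, 9.0, 500.0)])


class TestFitIndividual:
    def test_noiseless_line_recovered_exactly(self):
        cal = fit_individual(make_linear_session(BETA0, BETA1))
        assert cal.intercept == pytest.approx(BETA0, abs=1e-10)
        assert cal.slope == pytest.approx(BETA1, abs=1e-12)
        assert cal.pearson_r == pytest.approx(1.0)
        assert cal.see == pytest.approx(0.0, abs=1e-10)

    def test_flat_response_reports_zero_r_with_warning(self):
        cal_session = make_linear_session(2.0, 0.0)
        with pytest.warns(UserWarning, match="constant MET"):
            cal = fit_individual(cal_session)
        assert cal.slope == pytest.approx(0.0, abs=1e-12)
        assert cal.pearson_r == 0.0

    def test_two_stages_insufficient(self):
        s = compute_mets(CalibrationSession("a", 3.0, [
            StageRecord(2.0, 7.0, 400.0), StageRecord(3.0, 9.0, 900.0)]))
        with pytest.raises(ValueError, match="3 stages"):
            fit_individual(s)

    def test_constant_counts_singular(self):
        s = compute_mets(CalibrationSession("a", 3.0, [
            StageRecord(2.0, 7.0, 500.0), StageRecord(3.0, 9.0, 500.0),
            StageRecord(4.0, 11.0, 500.0)]))
        with pytest.raises(SingularFitError):
            fit_individual(s)

    def test_quadratic_fit_recovers_quadratic_truth(self):
        counts = np.array([200.0, 600.0, 1000.0, 1400.0, 1800.0])
        a, b, d = 1.8, 0.0004, 2e-7
        rvo2 = 3.0
        stages = [StageRecord(speed=v, vo2=(a + b * c + d * c**2) * rvo2, counts_per_min=c)
                  for v, c in zip([2, 3, 4, 5, 6], counts)]
        cal = fit_individual(compute_mets(CalibrationSession("q", rvo2, stages)),
                             order="quadratic")
        assert cal.intercept == pytest.approx(a, rel=1e-8)
        assert cal.slope == pytest.approx(b, rel=1e-8)
        assert cal.quad_coef == pytest.approx(d, rel=1e-8)


class TestDeriveIcp:
    def test_published_model_gives_685_after_rounding(self):
        cal = SubjectCalibration("g", intercept=BETA0, slope=BETA1, pearson_r=1.0, see=0.0)
        out = derive_icp(cal)
        assert out.icp == pytest.approx((3 - BETA0) / BETA1)
        assert round(out.icp) == 685
        assert not out.floor_applied

    @pytest.mark.parametrize("a, b", [(3.5, 0.001), (3.0, 0.001)])
    def test_nonpositive_crossing_floored_at_100(self, a, b):
        out = derive_icp(SubjectCalibration("f", a, b, 1.0, 0.0))
        assert out.icp == 100.0
        assert out.floor_applied

    def test_zero_slope_has_no_crossing(self):
        with pytest.raises(ZeroDivisionError):
            derive_icp(SubjectCalibration("z", 2.0, 0.0, 0.0, 0.0))

    def test_negative_slope_warns_but_computes(self):
        with pytest.warns(UserWarning, match="implausible"):
            out = derive_icp(SubjectCalibration("n", 4.0, -0.001, -1.0, 0.0))
        assert out.icp == pytest.approx(1000.0)

    def test_inverts_fit_for_noiseless_data(self):
        for true_icp in (300.0, 685.0, 2400.0):
            b = 0.0007
            a = 3.0 - b * true_icp
            cal = derive_icp(fit_individual(make_linear_session(a, b)))
            assert cal.icp == pytest.approx(true_icp, rel=1e-6)

    def test_quadratic_mode_smallest_positive_root(self):
        # 2 + 0.001 c + 1e-7 c^2 = 3 -> c = 732.05
        cal = SubjectCalibration("q", 2.0, 0.001, 1.0, 0.0,
                                 model_order="quadratic", quad_coef=1e-7)
        out = derive_icp(cal)
        roots = np.roots([1e-7, 0.001, -1.0])
        expected = min(r.real for r in roots if r.real > 0)
        assert out.icp == pytest.approx(expected)


class TestSpeedAtMet:
    def session_with_mets(self, mets, speeds):
        rvo2 = 3.0
        stages = [StageRecord(speed=v, vo2=m * rvo2, counts_per_min=300.0 * v)
                  for v, m in zip(speeds, mets)]
        return compute_mets(CalibrationSession("s", rvo2, stages))

    def test_node_hit(self):
        s = self.session_with_mets([2.0, 3.0], [2.0, 3.0])
        assert speed_at_met(s, 3.0) == pytest.approx(3.0)

    def test_midpoint_interpolation(self):
        s = self.session_with_mets([2.5, 3.5], [2.0, 3.0])
        assert speed_at_met(s, 3.0) == pytest.approx(2.5)

    def test_extrapolation_below_first_stage(self):
        # already above 3 METs at 2 km/h, as for the slowest walkers
        s = self.session_with_mets([3.2, 4.0, 4.8], [2.0, 3.0, 4.0])
        v = speed_at_met(s, 3.0)
        assert v < 2.0
        assert v == pytest.approx(2.0 + (3.0 - 3.2) / 0.8)

    def test_monotone_in_target(self):
        s = self.session_with_mets([2.1, 2.8, 3.4, 4.1, 4.9], [2, 3, 4, 5, 6])
        targets = np.linspace(2.2, 4.8, 12)
        speeds = [speed_at_met(s, t) for t in targets]
        assert all(b > a for a, b in zip(speeds, speeds[1:]))

    def test_non_monotone_profile_warns(self):
        s = self.session_with_mets([2.0, 3.5, 3.0, 4.0], [2, 3, 4, 5])
        with pytest.warns(UserWarning, match="non-monotone"):
            speed_at_met(s, 3.2)


class TestGroupModel:
    def test_noiseless_line_recovers_printed_coefficients(self):
        sessions = [
            make_linear_session(BETA0, BETA1, counts=tuple(c + 37 * i for c in
                                (200.0, 600.0, 1000.0, 1400.0, 1800.0)),
                                subject_id=f"s{i}")
            for i in range(6)
        ]
        gm = fit_group_model(sessions)
        assert gm.beta0 == pytest.approx(BETA0, abs=1e-4)
        assert gm.beta1 == pytest.approx(BETA1, rel=1e-4)
        assert gm.gcp_rounded == 685

    def test_duplicated_subject_equals_its_ols_fit(self):
        """Degenerate pooling: one subject's exact line, duplicated, is its OLS fit.

        With data on a line both the GLS and OLS fits interpolate it exactly,
        whatever within-subject covariance REML lands on.
        """
        s = make_linear_session(2.2, 0.0009)
        gm = fit_group_model([s, CalibrationSession("d2", s.resting_vo2, s.stages)])
        ols = sm.OLS(s.mets, sm.add_constant(s.counts)).fit()
        assert gm.beta0 == pytest.approx(ols.params[0], rel=1e-4)
        assert gm.beta1 == pytest.approx(ols.params[1], rel=1e-4)

    def test_profiled_beta_reduces_to_ols_when_variance_components_vanish(self):
        """With sigma2_u -> 0 and rho = 0 the GLS fixed effects are OLS exactly."""
        from accelcal.calibration import _reml_pieces

        ses, _ = generate_group_model_cohort(CohortScenario(), seed=0, n_subjects=15)
        ses = [compute_mets(s) for s in ses]
        groups = [(np.column_stack([np.ones(len(s.counts)), s.counts]), s.mets) for s in ses]
        _, beta, _ = _reml_pieces(np.array([np.log(1e-12), 0.0, np.log(0.02)]), groups)
        y = np.concatenate([g[1] for g in groups])
        X = np.vstack([g[0] for g in groups])
        bols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.max(np.abs(beta - bols) / np.abs(bols)) < 1e-4

    def test_iid_data_estimates_close_to_pooled_ols(self):
        scen = CohortScenario(group_sigma2_u=0.0, group_rho=0.0)
        ses, _ = generate_group_model_cohort(scen, seed=2, n_subjects=60)
        ses = [compute_mets(s) for s in ses]
        gm = fit_group_model(ses)
        y = np.concatenate([s.mets for s in ses])
        c = np.concatenate([s.counts for s in ses])
        ols = sm.OLS(y, sm.add_constant(c)).fit()
        assert gm.beta0 == pytest.approx(ols.params[0], rel=1e-2)
        assert gm.beta1 == pytest.approx(ols.params[1], rel=1e-2)

    def test_reml_objective_not_worse_than_truth(self):
        scen = CohortScenario()
        gaps = []
        for seed in range(8):
            ses, truth = generate_group_model_cohort(scen, seed=100 + seed, n_subjects=30)
            ses = [compute_mets(s) for s in ses]
            gm = fit_group_model(ses)
            nll_est = reml_negloglik(ses, gm.sigma2_u, gm.rho, gm.sigma2_e)
            nll_truth = reml_negloglik(ses, truth["sigma2_u"], truth["rho"], truth["sigma2_e"])
            gaps.append(nll_est - nll_truth)
        assert np.mean(gaps) <= 1e-6  # maximizer at least as good as truth on average

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match=">= 2 subjects"):
            fit_group_model([make_linear_session(BETA0, BETA1)])

    def test_parameter_recovery_on_small_batch(self):
        scen = CohortScenario()
        est = []
        for seed in range(12):
            ses, _ = generate_group_model_cohort(scen, seed=500 + seed, n_subjects=40)
            gm = fit_group_model([compute_mets(s) for s in ses])
            est.append([gm.beta0, gm.beta1, gm.sigma2_u, gm.rho, gm.sigma2_e])
        mean = np.mean(est, axis=0)
        assert mean[0] == pytest.approx(BETA0, abs=0.15)
        assert mean[1] == pytest.approx(BETA1, rel=0.15)
        assert mean[2] == pytest.approx(0.04, abs=0.03)
        assert mean[3] == pytest.approx(0.5, abs=0.3)
        assert mean[4] == pytest.approx(0.02, abs=0.015)
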