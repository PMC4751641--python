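import numpy as np
import pytest
from scipy import stats, optimize

import nphtest as nt
from nphtest.classical_tests import ConvergenceError, _gt_statistic
from nphtest.survdata import DataError


FOUR_SUBJECTS = nt.SurvivalData([1.0, 3.0, 2.0, 4.0], [1, 1, 1, 1], [0, 0, 1, 1])


def four_subject_loglik(beta):
    """Written-out Breslow partial likelihood for the 4-subject example."""
    eb = np.exp(beta)
    return (
        (0 - np.log(2 + 2 * eb))       # t=1, event in arm 0, risk set 2+2
        + (beta - np.log(1 + 2 * eb))  # t=2, event in arm 1, risk set 1+2
        + (0 - np.log(1 + eb))         # t=3, event in arm 0, risk set 1+1
        + (beta - np.log(eb))          # t=4, event in arm 1, alone at risk
    )


class TestCox:
    def test_identical_arms_null(self):
        t = list(np.arange(1.0, 31.0))
        d = nt.SurvivalData(t + t, [1] * 60, [0] * 30 + [1] * 30)
        fit = nt.cox_fit(d)
        assert abs(fit.beta) < 1e-6
        assert fit.chi2_plr < 1e-10

    def test_four_subject_grid_search_oracle(self):
        fit = nt.cox_fit(FOUR_SUBJECTS)
        grid = np.linspace(-4, 4, 200001)
        beta_star = grid[np.argmax(four_subject_loglik(grid))]
        assert fit.beta == pytest.approx(beta_star, abs=1e-4)
        # and against a proper 1-d maximizer
        res = optimize.minimize_scalar(lambda b: -four_subject_loglik(b), bounds=(-4, 4), method="bounded",
                                       options={"xatol": 1e-10})
        assert fit.beta == pytest.approx(res.x, abs=1e-6)

    def test_plr_chi2_from_written_out_likelihood(self):
        fit = nt.cox_fit(FOUR_SUBJECTS)
        chi2 = 2 * (four_subject_loglik(fit.beta) - four_subject_loglik(0.0))
        assert fit.chi2_plr == pytest.approx(chi2, abs=1e-10)

    def test_label_flip_negates_beta(self, early_fixture):
        d = early_fixture(n_per_arm=100, seed=31)
        a = nt.cox_fit(d)
        b = nt.cox_fit(d.with_arm(1 - d.arm))
        assert a.beta == pytest.approx(-b.beta, abs=1e-8)
        assert a.chi2_plr == pytest.approx(b.chi2_plr, abs=1e-8)

    def test_large_sample_hr_recovery(self):
        d = nt.make_fixture(
            nt.FixtureSpec(family="exponential", n_per_arm=20000, effect="ph", hr=0.75, seed=32)
        )
        assert 0.72 < nt.cox_fit(d).hr < 0.78

    def test_monotone_likelihood_flagged(self):
        d = nt.SurvivalData([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0], [0, 0, 1, 1])
        with pytest.raises(ConvergenceError):
            nt.cox_fit(d)

    def test_efron_matches_lifelines_on_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(33)
        t = np.ceil(rng.exponential(1.0, 200) * 4) / 4  # heavy ties
        arm = np.repeat([0, 1], 100)
        t[arm == 1] *= 1.3
        d = nt.SurvivalData(t, np.ones(200, int), arm)
        fit = nt.cox_fit(d, ties="efron")
        cph = CoxPHFitter().fit(d.to_frame(), "time", "event")
        assert fit.beta == pytest.approx(float(cph.params_["arm"]), abs=1e-6)
        assert fit.se == pytest.approx(float(cph.standard_errors_["arm"]), abs=1e-6)


class TestLogrank:
    def test_identical_arms_zero(self):
        t = list(np.arange(1.0, 21.0))
        d = nt.SurvivalData(t + t, [1] * 40, [0] * 20 + [1] * 20)
        chi2, p = nt.logrank_test(d)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_equals_cox_score_breslow(self, null_fixture, ph_fixture, early_fixture):
        # tie-free data: logrank chisquare == Cox score chisquare exactly
        for d in (null_fixture(150, seed=1), ph_fixture(150, seed=2), early_fixture(150, seed=3)):
            chi2, _ = nt.logrank_test(d)
            assert chi2 == pytest.approx(nt.cox_score_chi2(d), abs=1e-8)

    def test_label_swap_invariance(self, ph_fixture):
        d = ph_fixture(100, seed=4)
        a, _ = nt.logrank_test(d)
        b, _ = nt.logrank_test(d.with_arm(1 - d.arm))
        assert a == pytest.approx(b, rel=1e-12)

    def test_single_arm_rejected(self):
        with pytest.raises(DataError):
            nt.logrank_test(nt.SurvivalData([1.0, 2.0], [1, 1], [0, 0]))


class TestSchoenfeld:
    def test_raw_residuals_sum_to_zero(self, early_fixture):
        d = early_fixture(n_per_arm=120, seed=41)
        fit = nt.cox_fit(d)
        _, _, raw = nt.schoenfeld_scaled_residuals(fit, d)
        assert abs(raw.sum()) < 1e-8  # score equation at the maximizer

    def test_four_subject_risk_set_expectations(self):
        fit = nt.cox_fit(FOUR_SUBJECTS)
        times, scaled, raw = nt.schoenfeld_scaled_residuals(fit, FOUR_SUBJECTS)
        eb = np.exp(fit.beta)
        expected = [
            0 - 2 * eb / (2 + 2 * eb),   # event in arm 0, risk set {2 ctl, 2 res}
            1 - 2 * eb / (1 + 2 * eb),   # event in arm 1, risk set {1 ctl, 2 res}
            0 - eb / (1 + eb),           # event in arm 0, risk set {1 ctl, 1 res}
            1 - eb / eb,                 # last subject alone at risk
        ]
        np.testing.assert_allclose(raw, expected, atol=1e-10)
        np.testing.assert_allclose(scaled, fit.beta + 4 * raw / fit.info, atol=1e-10)

    def test_single_event_rejected(self):
        d = nt.SurvivalData([1.0, 2.0, 3.0], [1, 0, 0], [0, 1, 1])
        fit_like = nt.cox_fit(
            nt.SurvivalData([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], [0, 1, 0, 1])
        )
        with pytest.raises(DataError):
            nt.schoenfeld_scaled_residuals(fit_like, d)


class TestGrambschTherneau:
    # Values from survival::cox.zph in R on the fixture below (transform as
    # named, global=FALSE).  cox.zph weights each event by its own risk-set
    # variance where the classic statistic uses the average information per
    # event, so agreement is to ~1 %, not machine precision.
    R_COXZPH = {"identity": 10.66971822, "rank": 11.73957900, "km": 11.73957900}

    @staticmethod
    def fixture():
        return nt.make_fixture(
            nt.FixtureSpec(family="weibull", n_per_arm=60, effect="early", rate=0.7,
                           shape=1.2, hr_early=0.4, hr_late=1.3, censor_horizon=3.0, seed=42)
        )

    @pytest.mark.parametrize("transform", ["identity", "rank", "km"])
    def test_against_r_coxzph(self, transform):
        d = self.fixture()
        gt = nt.grambsch_therneau(nt.cox_fit(d), d, transform)
        assert gt.chi2_gt == pytest.approx(self.R_COXZPH[transform], rel=0.015)

    def test_constant_residuals_give_zero(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        raw = np.full(4, 0.25) - 0.25  # centred constant series
        assert _gt_statistic(g, raw, n_events=4, info=1.0) == pytest.approx(0.0, abs=1e-14)

    def test_affine_transform_invariance(self):
        # evenly spaced tie-free event times: rank transform is affine in time
        d = nt.SurvivalData(
            np.arange(1.0, 41.0), np.ones(40, int), np.tile([0, 1], 20)
        )
        fit = nt.cox_fit(d)
        a = nt.grambsch_therneau(fit, d, "identity")
        b = nt.grambsch_therneau(fit, d, "rank")
        assert a.chi2_gt == pytest.approx(b.chi2_gt, rel=1e-10)

    def test_all_events_tied_rejected(self):
        d = nt.SurvivalData([1.0, 1.0, 1.0, 1.0, 2.0], [1, 1, 1, 1, 0], [0, 1, 0, 1, 1])
        fit = nt.cox_fit(d)
        with pytest.raises(DataError):
            nt.grambsch_therneau(fit, d)

    def test_type1_error_calibrated_under_ph(self):
        # identical exponential arms: GT should reject at ~nominal 5 %
        reps, hits = 1000, 0
        seeds = np.random.SeedSequence(77).generate_state(1000) % (2**31)
        for i in range(reps):
            d = nt.make_fixture(
                nt.FixtureSpec(family="exponential", n_per_arm=2000, rate=1.0,
                               censor_horizon=float(np.log(2.5)), seed=int(seeds[i]))
            )
            fit = nt.cox_fit(d)
            hits += nt.grambsch_therneau(fit, d).p_gt <= 0.05
        frac = hits / reps
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


class TestJointTest:
    def test_two_df_closed_form(self):
        chi2, p = nt.joint_test(
            _cox_stub(chi2_plr=3.84), _gt_stub(chi2_gt=0.0)
        )
        assert p == pytest.approx(np.exp(-1.92), abs=1e-12)

    def test_double_null(self):
        _, p = nt.joint_test(_cox_stub(chi2_plr=0.0), _gt_stub(chi2_gt=0.0))
        assert p == 1.0

    def test_monotone_in_each_component(self):
        base = nt.joint_test(_cox_stub(2.0), _gt_stub(1.0))[1]
        assert nt.joint_test(_cox_stub(3.0), _gt_stub(1.0))[1] < base
        assert nt.joint_test(_cox_stub(2.0), _gt_stub(2.0))[1] < base

    def test_agrees_with_chi2_sf(self):
        chi2, p = nt.joint_test(_cox_stub(2.5), _gt_stub(1.7))
        assert p == pytest.approx(stats.chi2.sf(4.2, 2), rel=1e-12)


def _cox_stub(chi2_plr):
    return nt.CoxResult(beta=0.0, se=1.0, hr=1.0, chi2_plr=chi2_plr,
                        p_cox=float(stats.chi2.sf(chi2_plr, 1)), info=1.0,
                        n_events=10, ties="breslow", n_iter=1)


def _gt_stub(chi2_gt):
    return nt.GTResult(chi2_gt=chi2_gt, p_gt=float(stats.chi2.sf(chi2_gt, 1)),
                       time_transform="identity")
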