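import numpy as np
import pytest
from scipy import stats

import nphtest as nt
from nphtest import rp_sim
from nphtest.survdata import DataError


def one_arm(times):
    n = len(times)
    return nt.SurvivalData(times, np.ones(n, int), np.zeros(n, int))


class TestFitRP:
    def test_exponential_survival_recovered(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(2.0, 5000)  # rate 0.5
        fit = rp_sim.fit_rp(one_arm(t), df=3)
        for q in (0.25, 0.5, 0.75):
            tt = float(np.quantile(t, q))
            assert fit.survival(tt) == pytest.approx(np.exp(-0.5 * tt), abs=0.02)

    def test_df1_nests_weibull_slope_one_for_exponential(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1.0, 5000)
        fit = rp_sim.fit_rp(one_arm(t), df=1)
        assert 0.95 < fit.coef[1] < 1.05

    def test_too_few_events_rejected(self):
        with pytest.raises(DataError):
            rp_sim.fit_rp(one_arm([1.0, 2.0, 3.0]), df=3)

    def test_round_trip_survival_recovery(self):
        # draws from a known model refit to within 0.02 sup-norm (inner 90 %)
        truth = rp_sim.default_control_model(0.4)
        draws = truth.simulate(10_000, np.random.default_rng(3))
        fit = rp_sim.fit_rp(one_arm(draws), df=3)
        grid = np.quantile(draws, np.linspace(0.05, 0.95, 50))
        err = np.abs(fit.survival(grid) - truth.survival(grid))
        assert err.max() < 0.02


class TestCensoringModel:
    def test_no_censoring_sentinel(self):
        assert rp_sim.fit_censoring_model(one_arm([1.0, 2.0, 3.0, 4.0, 5.0])) is None

    def test_single_time_point_mass(self):
        d = nt.SurvivalData([1.0, 2.0, 3.0, 3.0, 3.0], [1, 1, 0, 0, 0], [0] * 5)
        model = rp_sim.fit_censoring_model(d)
        assert isinstance(model, rp_sim.PointMassCensoring)
        assert model.time == 3.0
        np.testing.assert_array_equal(
            model.simulate(4, np.random.default_rng(0)), [3.0] * 4
        )

    def test_uniform_censoring_distribution_recovered(self):
        rng = np.random.default_rng(4)
        event = rng.exponential(50.0, 4000)  # almost nothing fails first
        cens = rng.uniform(0.0, 5.0, 4000)
        obs = np.minimum(event, cens)
        d = nt.SurvivalData(obs, (event <= cens).astype(int), np.zeros(4000, int))
        # a uniform's hazard blows up at its upper limit; give the spline
        # enough knots to bend there
        model = rp_sim.fit_censoring_model(d, df=5)
        grid = np.linspace(0.5, 4.5, 30)
        np.testing.assert_allclose(model.survival(grid), 1 - grid / 5.0, atol=0.03)


class TestSimulate:
    def test_exponential_model_mean(self):
        m = rp_sim.default_control_model(1.0)
        x = rp_sim.simulate_survival(m, 100_000, seed=5)
        assert abs(x.mean() - 1.0) < 3.0 / np.sqrt(100_000)

    def test_ks_against_model_cdf(self):
        m = rp_sim.RPModel(np.log([0.1, 10.0]), np.array([-0.5, 1.3]))  # Weibull-ish
        x = rp_sim.simulate_survival(m, 10_000, seed=6)
        ks = stats.kstest(x, lambda t: 1 - m.survival(t))
        assert ks.statistic < 0.02

    def test_seed_determinism(self):
        m = rp_sim.default_control_model(0.3)
        a = rp_sim.simulate_survival(m, 1000, seed=7)
        b = rp_sim.simulate_survival(m, 1000, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_json_round_trip(self):
        m = rp_sim.RPModel(np.log([0.1, 1.0, 3.0, 10.0]), np.array([-0.4, 1.1, 0.02, -0.01]))
        back = rp_sim.RPModel.from_json(m.to_json())
        np.testing.assert_allclose(back.knots, m.knots)
        np.testing.assert_allclose(back.coef, m.coef)


class TestPHShift:
    def test_zero_shift_identity(self):
        m = rp_sim.default_control_model(0.25)
        s = rp_sim.apply_ph_shift(m, 0.0)
        np.testing.assert_array_equal(s.coef, m.coef)

    def test_cumulative_hazard_scaled_exactly(self):
        rng = np.random.default_rng(8)
        fit = rp_sim.fit_rp(one_arm(rng.exponential(1.0, 2000)), df=3)
        sh = rp_sim.apply_ph_shift(fit, np.log(0.75))
        ts = np.linspace(0.05, 5.0, 50)
        np.testing.assert_allclose(sh.cum_hazard(ts) / fit.cum_hazard(ts), 0.75, atol=1e-12)

    def test_shift_commutes_with_simulation(self):
        # shifted-model draws match inverse-CDF-transformed control draws
        m = rp_sim.default_control_model(0.5)
        sh = rp_sim.apply_ph_shift(m, np.log(0.6))
        a = sh.simulate(10_000, np.random.default_rng(9))
        # exponential: H -> 0.6 H means T -> T / 0.6
        b = m.simulate(10_000, np.random.default_rng(10)) / 0.6
        assert stats.ks_2samp(a, b).statistic < 0.02


class TestLateEffect:
    def test_zero_theta_unit_hazard_ratio(self):
        le = rp_sim.apply_late_effect(rp_sim.default_control_model(0.25), theta=0.0)
        np.testing.assert_allclose(le.hr_function(np.geomspace(0.1, 20, 50)), 1.0, atol=1e-12)

    def test_default_shape_constraints(self):
        le = rp_sim.apply_late_effect(rp_sim.default_control_model(0.25))
        early = np.linspace(0.02, 1.0, 200)
        assert np.abs(le.hr_function(early) - 1.0).max() < 0.02
        assert le.hr_function(np.array([3.0]))[0] < 0.8
        assert (le.hr_function(np.linspace(1.01, 50, 300)) < 1.0).all()

    def test_pathological_parameters_rejected(self):
        with pytest.raises(ValueError, match="nonpositive hazard"):
            rp_sim.apply_late_effect(rp_sim.default_control_model(0.25), theta=3.0, tau=0.05)

    def test_analytic_hr_matches_nelson_aalen_finite_difference(self):
        ctrl = rp_sim.default_control_model(0.25)
        le = rp_sim.apply_late_effect(ctrl)
        n = 100_000
        rng = np.random.default_rng(12)
        t0s, t1s = ctrl.simulate(n, rng), le.simulate(n, rng)
        grid = np.linspace(1.0, 5.0, 6)  # wide intervals keep the MC noise small
        # empirical cumulative-hazard increments per arm over each interval
        def increments(x):
            s = np.array([np.mean(x > g) for g in grid])
            return np.diff(-np.log(s))
        hr_emp = increments(t1s) / increments(t0s)
        mid = 0.5 * (grid[:-1] + grid[1:])
        np.testing.assert_allclose(hr_emp, le.hr_function(mid), atol=0.03)


class TestScenarios:
    def test_scenario_a_split_is_exchangeable(self):
        # random 1:1 split of one sample: logrank at 5 % rejects ~5 %
        ctrl = rp_sim.default_control_model(0.25)
        cens = rp_sim.UniformAccrualCensoring(4.0, 8.0)
        seeds = np.random.SeedSequence(13).generate_state(1000) % (2**31)
        hits = 0
        for i in range(1000):
            d = rp_sim.scenario_generate(
                rp_sim.ScenarioSpec(scenario="A", n=500, control=ctrl, censoring=cens,
                                    seed=int(seeds[i]))
            )
            hits += nt.logrank_test(d)[1] <= 0.05
        assert abs(hits / 1000 - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1000)

    def test_scenario_b_large_sample_hazard_ratio(self):
        d = rp_sim.scenario_generate(
            rp_sim.ScenarioSpec(scenario="B", n=40_000, seed=11,
                                censoring=rp_sim.UniformAccrualCensoring(4.0, 8.0))
        )
        assert 0.72 < nt.cox_fit(d).hr < 0.78

    def test_scenario_c_shows_nonproportional_hazards(self):
        cens = rp_sim.UniformAccrualCensoring(4.0, 8.0)
        hits = 0
        for i in range(100):
            d = rp_sim.scenario_generate(
                rp_sim.ScenarioSpec(scenario="C", n=2000, censoring=cens, seed=500 + i)
            )
            hits += nt.grambsch_therneau(nt.cox_fit(d), d).p_gt <= 0.05
        assert hits > 50

    def test_scenario_d_reduces_late_hazard(self):
        d = rp_sim.scenario_generate(rp_sim.ScenarioSpec(scenario="D", n=40_000, seed=14))
        # survival beyond t=4 must be higher in the research arm; t<1 similar
        s0, s1 = d.subset(0), d.subset(1)
        assert np.mean(s1.time > 4.0) > np.mean(s0.time > 4.0) + 0.02
        assert abs(np.mean(s1.time > 0.75) - np.mean(s0.time > 0.75)) < 0.01

    def test_generated_data_pass_invariants_and_determinism(self):
        spec = rp_sim.ScenarioSpec(scenario="C", n=300, seed=15,
                                   censoring=rp_sim.PointMassCensoring(5.0))
        a, b = rp_sim.scenario_generate(spec), rp_sim.scenario_generate(spec)
        np.testing.assert_array_equal(a.time, b.time)
        assert set(np.unique(a.event)) <= {0, 1}
        assert (a.time > 0).all()

    def test_early_effect_models_have_crossing_hazard_ratio(self):
        ctrl, res = rp_sim.make_early_effect_models()
        ts = np.array([0.3, 1.0])
        late = np.array([6.0, 8.0])
        assert (res.hazard(ts) / ctrl.hazard(ts) < 0.7).all()
        assert (res.hazard(late) / ctrl.hazard(late) > 1.0).all()
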