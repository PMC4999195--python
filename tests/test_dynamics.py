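import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapsched.branching_sim import simulate_compartment
from hapsched.dynamics import (
    CompartmentDynamics,
    RateFunctions,
    aggregate,
    conditional_burden,
    evaluate_schedule,
    extinction_prob,
    mean_resistant,
    mean_sensitive,
    mutant_influx,
    prob_resistance,
    recurrence_time,
)
from hapsched.schedule import DoseEvent, Schedule
from tests.conftest import exact_mutation_rates


class TestMeanSensitive:
    def test_constant_rate_closed_form(self):
        rf = RateFunctions.constant(0.02, 0.01, 0.0, 0.0)
        assert mean_sensitive(1000, rf, 100.0) == pytest.approx(1000 * np.e, rel=1e-10)

    def test_zero_rates_constant_population(self):
        rf = RateFunctions.constant(0.0, 0.0, 0.0, 0.0)
        for t in (0.0, 10.0, 500.0):
            assert mean_sensitive(123, rf, t) == 123.0

    def test_two_phase_piecewise_exponential(self):
        # r1 = +0.03 for 40 h then r2 = -0.01: closed form exp(r1*40 + r2*(t-40))
        rf = RateFunctions.piecewise_constant(
            [40.0], [(0.05, 0.02, 0, 0), (0.04, 0.05, 0, 0)]
        )
        t = 100.0
        expected = 500 * np.exp(0.03 * 40 - 0.01 * 60)
        assert mean_sensitive(500, rf, t) == pytest.approx(expected, rel=1e-8)


class TestMutantInflux:
    def test_zero_mutation_rate(self):
        rf = RateFunctions.constant(0.05, 0.01, 0.04, 0.01)
        assert mutant_influx(100, rf, 30.0, 0.0) == 0.0

    def test_constant_rate_closed_form(self):
        rf = RateFunctions.constant(0.05, 0.01, 0.04, 0.01)
        u, t = 1e-6, 50.0
        expected = 100 * np.exp(0.04 * t) * 0.05 * u
        assert mutant_influx(100, rf, t, u) == pytest.approx(expected, rel=1e-9)

    def test_influx_identity_with_mean(self):
        rf = RateFunctions.piecewise_constant([20.0], [(0.06, 0.02, 0, 0), (0.01, 0.03, 0, 0)])
        u = 1e-5
        for t in (5.0, 20.0, 33.0):
            ratio = mutant_influx(50, rf, t, u) / mean_sensitive(50, rf, t)
            assert ratio == pytest.approx(rf.lam_X(t) * u, rel=1e-9)


class TestExtinctionProbability:
    def test_pure_death_closed_form(self):
        mu = 0.1
        rf = RateFunctions.constant(0, 0, 0.0, mu)
        assert extinction_prob(rf, 0.0, 10.0) == pytest.approx(1 - np.exp(-1.0), abs=1e-9)

    def test_critical_closed_form(self):
        m = 0.05
        rf = RateFunctions.constant(0, 0, m, m)
        tau = 25.0
        assert extinction_prob(rf, 0.0, tau) == pytest.approx(m * tau / (1 + m * tau), abs=1e-9)

    @pytest.mark.parametrize("lam, mu", [(0.07, 0.11), (0.11, 0.07), (0.09, 0.09001)])
    def test_linear_birth_death_closed_form_all_regimes(self, lam, mu):
        # classic formula mu(e^{rt}-1)/(lam e^{rt}-mu), r = lam-mu
        tau = 30.0
        rf = RateFunctions.constant(0, 0, lam, mu)
        r = lam - mu
        expected = mu * (np.exp(r * tau) - 1) / (lam * np.exp(r * tau) - mu)
        assert extinction_prob(rf, 0.0, tau) == pytest.approx(expected, abs=1e-6)

    def test_time_shift_uses_rates_after_founding(self):
        rf = RateFunctions.piecewise_constant([10.0], [(0, 0, 0.0, 0.2), (0, 0, 0.0, 0.05)])
        # clone founded at T=10 sees only the 0.05 phase
        assert extinction_prob(rf, 10.0, 30.0) == pytest.approx(1 - np.exp(-1.0), abs=1e-9)


class TestMeanResistant:
    def test_zero_mutation_rate(self):
        rf = RateFunctions.constant(0.05, 0.01, 0.04, 0.01)
        assert mean_resistant(100, rf, 50.0, 0.0) == 0.0

    def test_critical_resistant_linear_growth(self):
        # lam_Y = mu_Y and X critical too: b constant, E[Y] = b*t
        rf = RateFunctions.constant(0.05, 0.05, 0.03, 0.03)
        u, t = 1e-4, 40.0
        b = 100 * 0.05 * u
        assert mean_resistant(100, rf, t, u) == pytest.approx(b * t, rel=1e-6)

    def test_against_simulation(self):
        rates = (0.06, 0.05, 0.05, 0.045)
        u, t, M0 = 1e-2, 30.0, 50
        rf_exact, u_eff = exact_mutation_rates(rates, u)
        ey = mean_resistant(M0, rf_exact, t, u_eff)
        sim = simulate_compartment(
            M0,
            RateFunctions.constant(*rates),
            u,
            t,
            4000,
            seed=2024,
            record_times=[0, t],
        )
        z = (ey - sim.mean_resistant[-1]) / sim.se_resistant[-1]
        assert abs(z) < 3.0


class TestProbResistance:
    def test_zero_mutation_rate(self):
        rf = RateFunctions.constant(0.05, 0.01, 0.04, 0.01)
        assert prob_resistance(100, rf, 50.0, 0.0) == 0.0

    def test_certain_extinction_gives_zero(self):
        # resistant cells die instantly relative to horizon: P ~ b/mu ~ 0
        rf = RateFunctions.constant(0.02, 0.02, 0.0, 1e4)
        assert prob_resistance(10, rf, 10.0, 1e-6) < 1e-6

    def test_against_simulation(self):
        rates = (0.06, 0.05, 0.05, 0.045)
        u, t, M0 = 1e-2, 30.0, 50
        rf_exact, u_eff = exact_mutation_rates(rates, u)
        p = prob_resistance(M0, rf_exact, t, u_eff)
        sim = simulate_compartment(
            M0,
            RateFunctions.constant(*rates),
            u,
            t,
            4000,
            seed=2024,
            record_times=[0, t],
        )
        p_hat = sim.fraction_resistant[-1]
        se = np.sqrt(p_hat * (1 - p_hat) / sim.n_effective)
        assert abs(p - p_hat) < 3 * se

    @settings(max_examples=15, deadline=None)
    @given(
        rates=st.tuples(
            st.floats(0.0, 0.1), st.floats(0.0, 0.1), st.floats(0.0, 0.1), st.floats(0.0, 0.1)
        ),
        u=st.floats(0.0, 1e-2),
        t=st.floats(1.0, 60.0),
    )
    def test_probability_in_unit_interval(self, rates, u, t):
        rf = RateFunctions.constant(*rates)
        p = prob_resistance(60, rf, t, u, n_grid=301)
        assert 0.0 <= p <= 1.0
        assert mean_sensitive(60, rf, t) >= 0.0
        assert mean_resistant(60, rf, t, u, n_grid=301) >= 0.0


class TestAggregation:
    def _cd(self, i, times, ex, ey, p):
        return CompartmentDynamics(
            compartment=i,
            times=np.asarray(times, dtype=float),
            mean_sensitive=np.asarray(ex, dtype=float),
            mean_resistant=np.asarray(ey, dtype=float),
            prob_resistance=np.asarray(p, dtype=float),
        )

    def test_single_compartment_identity(self):
        c = self._cd(1, [0, 1], [5, 6], [0, 1], [0.0, 0.3])
        res = aggregate([c])
        assert res.P == pytest.approx([0.0, 0.3])
        assert res.E_total == pytest.approx([5.0, 7.0])

    def test_product_rule(self):
        c1 = self._cd(1, [0.0], [1], [0], [0.5])
        c2 = self._cd(2, [0.0], [1], [0], [0.5])
        assert aggregate([c1, c2]).P[0] == pytest.approx(0.75)

    def test_aggregate_dominates_max(self):
        rng = np.random.default_rng(0)
        ps = rng.uniform(0, 1, size=(4, 6))
        comps = [self._cd(i + 1, np.arange(6), np.ones(6), np.zeros(6), ps[i]) for i in range(4)]
        agg = aggregate(comps)
        assert np.all(agg.P >= ps.max(axis=0) - 1e-12)
        assert np.all(agg.P <= 1.0)

    def test_misaligned_grids_rejected(self):
        c1 = self._cd(1, [0, 1], [1, 1], [0, 0], [0, 0])
        c2 = self._cd(2, [0, 2], [1, 1], [0, 0], [0, 0])
        with pytest.raises(ValueError, match="misaligned"):
            aggregate([c1, c2])


class TestRecurrenceAndBurden:
    def test_monotone_increase_never_recurs(self):
        t = np.linspace(0, 100, 201)
        assert recurrence_time(t, 100 * np.exp(0.01 * t), 100.0) is None

    def test_decline_then_regrowth(self):
        # decline at -0.01/h for 100 h then growth at +0.02/h: recurrence at 150 h
        t = np.unique(np.concatenate([np.linspace(0, 400, 801), [100.0]]))
        e = np.where(t <= 100, np.exp(-0.01 * t), np.exp(-1.0 + 0.02 * (t - 100)))
        assert recurrence_time(t, 1000 * e, 1000.0) == pytest.approx(150.0, abs=1e-9)

    def test_constant_at_M_never_recurs(self):
        t = np.linspace(0, 10, 11)
        assert recurrence_time(t, np.full_like(t, 50.0), 50.0) is None

    def test_conditional_burden_limits(self):
        assert conditional_burden(10.0, 5.0, 1.0) == pytest.approx(15.0)
        assert conditional_burden(10.0, 0.0, 0.5) == pytest.approx(10.0)
        assert np.isnan(conditional_burden(10.0, 0.0, 0.0))

    def test_conditional_burden_against_simulation(self):
        rates = (0.06, 0.05, 0.05, 0.045)
        u, t, M0 = 1e-2, 30.0, 60
        rf_exact, u_eff = exact_mutation_rates(rates, u)
        analytic = conditional_burden(
            mean_sensitive(M0, rf_exact, t),
            mean_resistant(M0, rf_exact, t, u_eff),
            prob_resistance(M0, rf_exact, t, u_eff),
        )
        sim = simulate_compartment(
            M0, RateFunctions.constant(*rates), u, t, 4000, seed=7, record_times=[0, t]
        )
        mean, se = sim.conditional_mean_burden()
        assert abs(analytic - mean) < 3 * se + 0.05 * mean


class TestScheduleEvaluation:
    def test_zero_drug_limit_grows_at_weighted_control_rate(
        self, compartment_model, rate_model
    ):
        # with no doses at all, each compartment grows exponentially at its
        # control net rate, so the total is the weighted mixture
        sched = Schedule((), cycle_hours=504.0)
        horizon = 100.0
        res = evaluate_schedule(compartment_model, rate_model, sched, horizon)
        expected = 0.0
        from hapsched.rate_models import SENSITIVE

        for c in compartment_model:
            lam, mu = rate_model.control_rates(SENSITIVE, c.index)
            expected += c.initial_sensitive * np.exp((lam - mu) * horizon)
        assert res.E_X[-1] == pytest.approx(expected, rel=1e-4)

    def test_quadrature_refinement_converges(self, compartment_model, rate_model, schedules):
        res1 = evaluate_schedule(
            compartment_model, rate_model, schedules["C"], 504.0,
            fine_step=0.04, coarse_step=0.5,
        )
        res2 = evaluate_schedule(
            compartment_model, rate_model, schedules["C"], 504.0,
            fine_step=0.02, coarse_step=0.25,
        )
        assert res1.E_total[-1] == pytest.approx(res2.E_total[-1], rel=1e-4)
        assert res1.P[-1] == pytest.approx(res2.P[-1], abs=1e-6)

    def test_probabilities_and_means_well_formed(
        self, compartment_model, rate_model, schedules
    ):
        res = evaluate_schedule(compartment_model, rate_model, schedules["E"], 504.0)
        assert np.all((res.P >= 0) & (res.P <= 1))
        assert np.all(res.E_X >= 0) and np.all(res.E_Y >= 0)
        np.testing.assert_allclose(res.E_total, res.E_X + res.E_Y, rtol=1e-12)
        # aggregation identity at every stored time point
        recomputed = 1.0 - np.prod(
            [1.0 - c.prob_resistance for c in res.per_compartment], axis=0
        )
        np.testing.assert_allclose(res.P, recomputed, atol=1e-12)

    def test_tidy_export(self, compartment_model, rate_model, schedules, tmp_path):
        res = evaluate_schedule(compartment_model, rate_model, schedules["A"], 168.0)
        df = res.to_frame()
        assert {"time_h", "compartment", "E_X", "E_Y", "P"} <= set(df.columns)
        assert "total" in set(df["compartment"])
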