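"""Off-path folding model: generator matrix, solvers, equilibrium, rates."""

import numpy as np
import pytest

from g4fret.kinetics import (
    P_STATES,
    STATE_INDEX,
    STATES,
    KineticModel,
    Occupancy,
    all_unfolded,
    delta_g,
    equilibrium,
    fit_rates,
    folded_fraction_curve,
    initial_partition,
    rate_matrix,
    sample_ctmc_path,
    simulate_gillespie,
    simulate_ode,
)

from conftest import random_model


class TestRateMatrix:
    def test_all_rates_zero_gives_zero_matrix(self):
        m = KineticModel(k_f=0, k_u=0, k_f2=0, k_u2=0)
        assert np.all(rate_matrix(m) == 0)

    def test_uniform_weights_split_total_nucleation_rate(self):
        m = KineticModel(k_f=1.0, k_u=0.3)
        Q = rate_matrix(m)
        u = STATE_INDEX["U"]
        off_diag = [Q[u, STATE_INDEX[p]] for p in P_STATES]
        assert np.allclose(off_diag, 1.0 / 5)
        assert np.isclose(Q[u, u], -1.0)

    def test_off_path_states_do_not_reach_f_directly(self, symmetric_model):
        Q = rate_matrix(symmetric_model)
        f = STATE_INDEX["F"]
        for p in ("P3", "P4", "P5"):
            assert Q[STATE_INDEX[p], f] == 0
            assert Q[f, STATE_INDEX[p]] == 0

    def test_rows_sum_to_zero_for_random_rates(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            Q = rate_matrix(random_model(rng))
            assert np.max(np.abs(Q.sum(axis=1))) < 1e-12


class TestInitialPartition:
    def test_terminal_positions_give_forty_percent_on_path(self, symmetric_model):
        occ, on_frac = initial_partition(symmetric_model)
        assert on_frac == pytest.approx(0.40, abs=1e-12)
        assert 1 - on_frac == pytest.approx(0.60, abs=1e-12)
        assert occ["U"] == 0 and occ["F"] == 0

    def test_degenerate_weights(self):
        m = KineticModel(k_f=1, k_u=1, nucleation_weights=(1, 0, 0, 0, 0))
        _, on_frac = initial_partition(m)
        assert on_frac == 1.0


class TestSimulateOde:
    def test_time_zero_returns_initial_condition(self, symmetric_model):
        p0 = all_unfolded()
        (out,) = simulate_ode(symmetric_model, p0, [0.0])
        assert np.allclose(out.probabilities, p0.probabilities, atol=1e-12)

    def test_long_time_matches_equilibrium(self, symmetric_model):
        eq = equilibrium(symmetric_model)
        (out,) = simulate_ode(symmetric_model, all_unfolded(), [1e4])
        assert np.max(np.abs(out.probabilities - eq.probabilities)) < 1e-6

    def test_agrees_with_forward_euler(self):
        # independent brute-force integrator as the oracle
        rng = np.random.default_rng(3)
        m = random_model(rng)
        Q = rate_matrix(m)
        dt = 1e-4 / np.max(np.abs(np.diag(Q)))
        t_end = 2.0
        p = all_unfolded().probabilities.copy()
        steps = int(round(t_end / dt))
        for _ in range(steps):
            p = p + dt * (p @ Q)
        (out,) = simulate_ode(m, all_unfolded(), [steps * dt])
        assert np.max(np.abs(out.probabilities - p)) < 1e-5

    def test_probability_conserved_and_nonnegative(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = random_model(rng)
            for occ in simulate_ode(m, all_unfolded(), [0.1, 1, 10, 100]):
                assert occ.probabilities.min() >= 0
                assert abs(occ.probabilities.sum() - 1) < 1e-8

    def test_unnormalized_p0_rejected(self, symmetric_model):
        with pytest.raises(ValueError):
            simulate_ode(symmetric_model, np.full(7, 0.5), [1.0])


class TestCtmcPath:
    def test_absorbing_model_single_segment(self):
        m = KineticModel(k_f=0, k_u=0)
        path = sample_ctmc_path(m, 10.0, "U", seed=0)
        assert path == [("U", 0.0)]

    def test_unknown_initial_state_named_in_error(self, symmetric_model):
        with pytest.raises(ValueError, match="P9"):
            sample_ctmc_path(symmetric_model, 1.0, "P9", seed=0)

    def test_mean_unfolded_holding_time(self):
        # first U dwell of each path is exponential with mean 1/k_f;
        # using only the first dwell avoids window-censoring bias
        m = KineticModel(k_f=1.0, k_u=1.0)
        rng = np.random.default_rng(42)
        holds = []
        for _ in range(3000):
            path = sample_ctmc_path(m, 30.0, "U", rng)
            if len(path) >= 2:
                holds.append(path[1][1] - path[0][1])
        holds = np.asarray(holds)
        se = holds.std(ddof=1) / np.sqrt(holds.size)
        assert abs(holds.mean() - 1.0) < 3 * se

    def test_first_jump_equipartition_over_positions(self):
        # k_f >> k_u: the first jump out of U picks a position uniformly
        m = KineticModel(k_f=50.0, k_u=1e-4)
        rng = np.random.default_rng(7)
        counts = dict.fromkeys(P_STATES, 0)
        n = 10_000
        for _ in range(n):
            path = sample_ctmc_path(m, 1.0, "U", rng)
            assert len(path) >= 2
            counts[path[1][0]] += 1
        from scipy.stats import chisquare

        stat, p = chisquare(list(counts.values()))
        assert p > 0.01


class TestGillespie:
    def test_zero_rates_constant_occupancy(self):
        m = KineticModel(k_f=0, k_u=0)
        occs, _ = simulate_gillespie(m, 100, [0.0, 1.0, 5.0], seed=0)
        for occ in occs:
            assert occ["U"] == 1.0

    def test_seed_determinism(self, symmetric_model):
        a, _ = simulate_gillespie(symmetric_model, 500, [0.5, 2.0], seed=123)
        b, _ = simulate_gillespie(symmetric_model, 500, [0.5, 2.0], seed=123)
        for x, y in zip(a, b):
            assert np.array_equal(x.probabilities, y.probabilities)

    def test_matches_ode_within_monte_carlo_error(self):
        rng = np.random.default_rng(5)
        m = random_model(rng, lo=0.05, hi=5.0)
        times = [0.2, 1.0, 5.0, 20.0]
        emp, se = simulate_gillespie(m, 10_000, times, seed=9)
        ode = simulate_ode(m, all_unfolded(), times)
        for i, (e, o) in enumerate(zip(emp, ode)):
            z = np.abs(e.probabilities - o.probabilities) / np.maximum(se[i], 1e-4)
            assert np.max(z) < 3.5


class TestEquilibrium:
    def test_symmetric_model_closed_form(self, symmetric_model):
        eq = equilibrium(symmetric_model)
        assert eq["U"] == pytest.approx(5 / 12, abs=1e-12)
        for p in P_STATES:
            assert eq[p] == pytest.approx(1 / 12, abs=1e-12)
        assert eq["F"] == pytest.approx(1 / 6, abs=1e-12)

    def test_no_second_folding_empties_f(self):
        m = KineticModel(k_f=1, k_u=2, k_f2=0, k_u2=0)
        assert equilibrium(m)["F"] == 0

    def test_closed_form_equals_nullspace(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            m = random_model(rng)
            a = equilibrium(m, "closed_form").probabilities
            b = equilibrium(m, "nullspace").probabilities
            assert np.max(np.abs(a - b)) < 1e-10

    def test_detailed_balance_on_every_edge(self):
        rng = np.random.default_rng(22)
        for _ in range(25):
            m = random_model(rng)
            pi = equilibrium(m).probabilities
            Q = rate_matrix(m)
            flux = pi[:, None] * Q
            assert np.max(np.abs(flux - flux.T)) < 1e-12

    def test_reducible_chain_rejected(self):
        with pytest.raises(ValueError):
            equilibrium(KineticModel(k_f=0, k_u=0))
        with pytest.raises(ValueError):
            equilibrium(KineticModel(k_f=1, k_u=1, k_f2=1, k_u2=0))


class TestFoldedFractionCurve:
    def test_all_unfolded_start_gives_zero_at_t0(self, symmetric_model):
        occs = simulate_ode(symmetric_model, all_unfolded(), [0.0, 1.0])
        tc = folded_fraction_curve(occs)
        assert tc.folded_fraction[0] == 0.0

    def test_symmetric_equilibrium_fraction(self, symmetric_model):
        eq = equilibrium(symmetric_model)
        tc = folded_fraction_curve([eq])
        assert tc.folded_fraction[0] == pytest.approx(1 / 6, abs=1e-10)

    def test_monotone_rise_from_unfolded_start(self):
        rng = np.random.default_rng(33)
        times = np.logspace(-2, 3, 25)
        for _ in range(25):
            m = random_model(rng)
            tc = folded_fraction_curve(simulate_ode(m, all_unfolded(), times))
            assert np.all(np.diff(tc.folded_fraction) > -1e-8)

    def test_full_on_path_exceeds_default_at_long_time(self, symmetric_model):
        # off-path states depress full folding: the model's core mechanism
        m_all = KineticModel(
            k_f=1, k_u=1, k_f2=1, k_u2=1, on_path=tuple(P_STATES)
        )
        t = [1e4]
        frac_all = folded_fraction_curve(simulate_ode(m_all, all_unfolded(), t))
        frac_def = folded_fraction_curve(
            simulate_ode(symmetric_model, all_unfolded(), t)
        )
        assert frac_all.folded_fraction[0] > frac_def.folded_fraction[0]

    def test_trapped_limit_equals_on_path_fraction(self):
        # without unfolding, molecules nucleating off-path stay stuck
        m = KineticModel(k_f=0.5, k_u=0.0, k_f2=1.0, k_u2=0.0)
        tc = folded_fraction_curve(simulate_ode(m, all_unfolded(), [1e4]))
        assert tc.folded_fraction[0] == pytest.approx(0.40, abs=1e-6)


class TestFitRates:
    @staticmethod
    def _observed(model, times, noise=0.0, seed=None):
        tc = folded_fraction_curve(simulate_ode(model, all_unfolded(), times))
        y = tc.folded_fraction
        if noise:
            rng = np.random.default_rng(seed)
            y = np.clip(y + noise * rng.standard_normal(y.size), 0, 1)
        from g4fret.kinetics import TimeCourse

        return TimeCourse(times, y, np.full(y.size, max(noise, 1e-3)))

    def test_noiseless_recovery_with_measured_kf(self, folding_model):
        # k_f is fixed at the independently measured unfolded-state rate
        # (1/lifetime of state 1); the remaining rates are then identifiable
        times = np.logspace(-1, 4, 20)
        obs = self._observed(folding_model, times)
        template = folding_model.with_rates(k_u=0.01, k_f2=0.01, k_u2=0.01)
        res = fit_rates(obs, template, fixed=("k_f",), seed=0)
        assert res.identifiable
        for name in ("k_f", "k_u", "k_f2", "k_u2"):
            true = getattr(folding_model, name)
            est = getattr(res.model, name)
            assert abs(est - true) / true < 0.05, name

    def test_four_free_rates_flagged_non_identifiable(self, folding_model):
        # the folded-fraction curve alone cannot distinguish which of the
        # two sequential folding steps is fast: the fit must say so
        times = np.logspace(-1, 4, 20)
        obs = self._observed(folding_model, times)
        template = folding_model.with_rates(k_f=0.01, k_u=0.01, k_f2=0.01, k_u2=0.01)
        with pytest.warns(RuntimeWarning, match="identifiable"):
            res = fit_rates(obs, template, seed=0)
        assert not res.identifiable

    def test_all_rates_fixed_returns_template(self, folding_model):
        times = np.array([1.0, 10.0, 100.0])
        obs = self._observed(folding_model, times)
        res = fit_rates(obs, folding_model, fixed=("k_f", "k_u", "k_f2", "k_u2"))
        assert res.model == folding_model
        assert res.dof == 0 and res.free == ()

    def test_unknown_fixed_rate_rejected(self, folding_model):
        times = np.array([1.0, 10.0, 100.0])
        obs = self._observed(folding_model, times)
        with pytest.raises(ValueError):
            fit_rates(obs, folding_model, fixed=("k_x",))


class TestDeltaG:
    def test_equal_rates_zero(self):
        assert delta_g(1.0, 1.0) == 0.0

    def test_rt_at_room_temperature(self):
        # ratio e at 298.15 K: dG = -R T = -2.479 kJ/mol
        assert delta_g(np.e, 1.0, 298.15) == pytest.approx(-2.479, abs=1e-3)

    def test_antisymmetry(self):
        assert delta_g(0.3, 2.0) == pytest.approx(-delta_g(2.0, 0.3), abs=1e-12)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            delta_g(0.0, 1.0)


class TestModelValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            KineticModel(k_f=-1, k_u=1)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            KineticModel(k_f=1, k_u=1, nucleation_weights=(0.5, 0.5, 0.5, 0, 0))

    def test_on_path_required_when_second_folding_active(self):
        with pytest.raises(ValueError):
            KineticModel(k_f=1, k_u=1, k_f2=1, k_u2=1, on_path=())

    def test_occupancy_must_normalize(self):
        with pytest.raises(ValueError):
            Occupancy(0.0, np.full(len(STATES), 0.2))
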