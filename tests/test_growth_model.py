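"""Unit and property tests for the two-compartment growth model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

from chemosched import (
    CompartmentParams,
    InvalidParameterError,
    ObjectiveConfig,
    StepKernel,
    alt_objective,
    default_config,
    episode_objective,
    initial_state,
    observation,
    propagate,
    sensitivity_table,
    steady_state_fraction,
    step_reward,
)
from chemosched.growth_model import PopulationState, rate_matrix


class TestSteadyStateFraction:
    @pytest.mark.parametrize(
        "tissue_fixture, expected, places",
        [("bm_params", 0.103, 3), ("breast_params", 0.200, 3), ("ovarian_params", 0.3600, 4)],
    )
    def test_published_fractions(self, tissue_fixture, expected, places, request):
        params = request.getfixturevalue(tissue_fixture)
        assert steady_state_fraction(params) == pytest.approx(expected, abs=0.5 * 10**-places)

    def test_root_satisfies_quadratic(self, bm_params):
        rho = steady_state_fraction(bm_params)
        a = bm_params.delta - bm_params.gamma - bm_params.lam
        b = bm_params.gamma + bm_params.lam - bm_params.beta - bm_params.alpha - bm_params.delta
        assert abs(a * rho**2 + b * rho + bm_params.beta) < 1e-10

    def test_no_return_from_quiescence_is_degenerate(self):
        # beta = 0 and alpha + delta > gamma + lam: the proliferative pool
        # drains irreversibly and the only root is 0, outside (0, 1)
        params = CompartmentParams(gamma=0.5, delta=0.3, alpha=0.9, beta=0.0, lam=0.1)
        with pytest.raises(InvalidParameterError):
            steady_state_fraction(params)


class TestInitialState:
    def test_ovarian_published_split(self, ovarian_params):
        state = initial_state(ovarian_params)
        assert state.P == pytest.approx(0.3600, abs=5e-5)
        assert state.Q == pytest.approx(0.6400, abs=5e-5)

    def test_masses_sum_to_one_exactly(self, bm_params, breast_params, ovarian_params):
        for params in (bm_params, breast_params, ovarian_params):
            state = initial_state(params)
            assert state.P + state.Q == pytest.approx(1.0, abs=1e-15)
            assert 0 < state.P < 1


class TestPropagate:
    def test_zero_time_is_identity(self, bm_params):
        state = initial_state(bm_params)
        assert propagate(state, bm_params, 0.5, 0.0) is state

    def test_untreated_ratio_is_stationary(self, bm_params, breast_params, ovarian_params):
        for params in (bm_params, breast_params, ovarian_params):
            rho = steady_state_fraction(params)
            state = initial_state(params)
            for dt in (0.5, 3.0, 21.0):
                out = propagate(state, params, 0.0, dt)
                assert out.P / (out.P + out.Q) == pytest.approx(rho, abs=1e-8)

    def test_matches_runge_kutta_oracle(self, bm_params):
        state = initial_state(bm_params)
        out = propagate(state, bm_params, 0.5, 21.0)
        A = rate_matrix(bm_params, 0.5)
        sol = solve_ivp(
            lambda t, x: A @ x, (0, 21.0), state.as_array(), rtol=1e-11, atol=1e-13
        )
        assert out.as_array() == pytest.approx(sol.y[:, -1], rel=1e-6)

    def test_step_composition(self, bm_params):
        state = initial_state(bm_params)
        one = propagate(propagate(state, bm_params, 0.3, 1.0), bm_params, 0.3, 1.0)
        two = propagate(state, bm_params, 0.3, 2.0)
        assert one.as_array() == pytest.approx(two.as_array(), abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        dose=st.floats(0.0, 1.0),
        dt=st.floats(0.01, 21.0),
        p=st.floats(0.0, 1.0),
    )
    def test_positive_orthant_is_invariant(self, bm_params, dose, dt, p):
        state = PopulationState(P=p, Q=1.0 - p)
        out = propagate(state, bm_params, dose, dt)
        assert out.P >= 0 and out.Q >= 0

    def test_rejects_invalid_dose_and_dt(self, bm_params):
        state = initial_state(bm_params)
        with pytest.raises(ValueError):
            propagate(state, bm_params, 1.5, 1.0)
        with pytest.raises(ValueError):
            propagate(state, bm_params, 0.5, -1.0)


class TestRewardAndObjective:
    def test_full_dose_has_no_penalty(self, bm_params):
        state = initial_state(bm_params)
        r = step_reward(state, bm_params, dose=1.0, b=5.0)
        r0 = step_reward(state, bm_params, dose=1.0, b=0.0)
        assert r == pytest.approx(r0, abs=1e-14)

    def test_penalty_separates_additively(self, bm_params):
        # R(b, dose) = population integral - b/2 (1-dose)^2, so adding the
        # penalty back must recover the b = 0 reward
        state = initial_state(bm_params)
        for dose in (0.0, 0.3, 1.0):
            r_b = step_reward(state, bm_params, dose=dose, b=5.0)
            r_0 = step_reward(state, bm_params, dose=dose, b=0.0)
            assert r_b + 5.0 / 2.0 * (1.0 - dose) ** 2 == pytest.approx(r_0, abs=1e-12)

    def test_step_rewards_sum_to_episode_objective(self, bm_params, cfg, rng):
        # J_b(f) must equal the sum of per-step rewards for any schedule
        for _ in range(100):
            schedule = rng.choice(cfg.actions, size=cfg.n_steps)
            total = 0.0
            state = initial_state(bm_params)
            for dose in schedule:
                total += step_reward(state, bm_params, float(dose), cfg.b, cfg.dt)
                state = propagate(state, bm_params, float(dose), cfg.dt)
            assert total == pytest.approx(episode_objective(schedule, bm_params, cfg), abs=1e-8)

    def test_untreated_objective_matches_quadrature(self, bm_params):
        cfg = default_config(b=0.0)
        J = episode_objective([0.0] * cfg.n_steps, bm_params, cfg)
        A = rate_matrix(bm_params, 0.0)
        x0 = initial_state(bm_params).as_array()
        sol = solve_ivp(
            lambda t, x: A @ x, (0, cfg.T), x0, rtol=1e-11, atol=1e-13, dense_output=True
        )
        oracle, _ = quad(lambda t: sol.sol(t).sum(), 0, cfg.T, limit=200)
        assert J == pytest.approx(oracle, abs=1e-7)

    def test_lower_doses_never_hurt_without_penalty(self, bm_params, rng):
        # with b = 0 the drug only removes mass, so pointwise-lower
        # schedules cannot score lower; checked over all 11^3 schedules
        cfg = default_config(b=0.0, T=3)
        idx = np.stack(np.meshgrid(*[np.arange(11)] * 3, indexing="ij"), axis=-1).reshape(-1, 3)
        kernel = StepKernel(bm_params, cfg)
        values = np.array([kernel.rollout(row) for row in idx])
        assert values.argmax() == 0  # the all-zero schedule is optimal
        for _ in range(300):
            i, j = rng.integers(len(idx), size=2)
            if np.all(idx[i] <= idx[j]):
                assert values[i] >= values[j] - 1e-12

    def test_schedule_length_mismatch_raises(self, bm_params, cfg):
        with pytest.raises(ValueError):
            episode_objective([0.0] * (cfg.n_steps - 1), bm_params, cfg)


class TestAltObjective:
    def test_zero_weight_reduces_to_marrow_integral(self, bm_params, breast_params):
        cfg = default_config(b=0.0)
        schedule = [0.5] * cfg.n_steps
        alt = alt_objective(schedule, bm_params, breast_params, cfg)
        assert alt == pytest.approx(episode_objective(schedule, bm_params, cfg), abs=1e-10)

    def test_identical_tissues_cancel_at_unit_weight(self, bm_params):
        cfg = default_config(b=1.0)
        schedule = [0.3] * cfg.n_steps
        assert alt_objective(schedule, bm_params, bm_params, cfg) == pytest.approx(0.0, abs=1e-10)

    def test_matches_quadrature_oracle(self, bm_params, breast_params, rng):
        cfg = default_config(b=0.7)
        schedule = rng.choice(cfg.actions, size=cfg.n_steps)

        def piecewise_integral(params):
            x = initial_state(params).as_array()
            total = 0.0
            for dose in schedule:
                A = rate_matrix(params, float(dose))
                sol = solve_ivp(
                    lambda t, x_: A @ x_, (0, cfg.dt), x, rtol=1e-11, atol=1e-13,
                    dense_output=True,
                )
                seg, _ = quad(lambda t: sol.sol(t).sum(), 0, cfg.dt, limit=100)
                total += seg
                x = sol.y[:, -1]
            return total

        oracle = piecewise_integral(bm_params) - cfg.b * piecewise_integral(breast_params)
        alt = alt_objective(schedule, bm_params, breast_params, cfg)
        assert alt == pytest.approx(oracle, abs=1e-6)


class TestObservation:
    def test_pretreatment_vector(self):
        obs = observation([1.0], t=0, wl=10)
        assert obs.vector.tolist() == [0.0] + [1.0] * 10
        assert len(obs) == 11

    def test_single_measurement_padding(self):
        obs = observation([1.0, 0.93], t=1, wl=10)
        assert obs.vector.tolist() == [1.0, 0.93] + [1.0] * 9

    def test_full_history_is_reverse_chronological(self):
        history = [1.0 - 0.01 * d for d in range(21)]
        obs = observation(history, t=20, wl=10)
        assert list(obs.window) == history[20:10:-1]

    def test_negative_day_rejected(self):
        with pytest.raises(ValueError):
            observation([1.0], t=-1)


class TestSensitivity:
    def test_growth_helps_and_death_hurts(self, bm_params, breast_params, ovarian_params):
        for params in (bm_params, breast_params, ovarian_params):
            table = sensitivity_table(params)
            assert table.loc["gamma", "P"] > 0
            if params.delta > 0:
                assert table.loc["delta", "P"] < 0

    def test_zero_rates_are_excluded(self, bm_params, breast_params):
        assert "delta" not in sensitivity_table(bm_params).index
        assert "lam" not in sensitivity_table(breast_params).index

    def test_first_order_stability_under_halved_step(self, breast_params):
        r1 = sensitivity_table(breast_params, dp=0.01)
        r2 = sensitivity_table(breast_params, dp=0.005)
        rel = ((r1 - r2).abs() / r1.abs()).to_numpy()
        assert np.all(rel < 0.1)
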