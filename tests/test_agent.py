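import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contpsych import (
    BPParams,
    WalkConfig,
    act_step,
    gen_random_walk,
    gen_session_walk,
    perceive,
    sense_step,
    simulate_session,
    simulate_training,
    steady_state_gain,
)
from contpsych.errors import ConfigError, DegenerateModelError, StabilityError
from contpsych.training import _step_response
from helpers import grid_posterior_means, steady_state_prior_variance


def iterated_gain(process_var: float, obs_var: float, n_iter: int = 10_000) -> float:
    """Independent oracle: iterate the Kalman variance recursion to its fixed point."""
    P = obs_var if obs_var > 0 else 1.0
    k = 0.0
    for _ in range(n_iter):
        S = P + process_var
        k = S / (S + obs_var)
        P = (1.0 - k) * S
    return k


class TestSteadyStateGain:
    def test_pure_prediction_and_pure_observation_limits(self):
        assert steady_state_gain(0.0, 1.0) == 0.0
        assert steady_state_gain(1.0, 0.0) == 1.0

    def test_equal_variances_gain_is_golden_ratio_conjugate(self):
        # fixed point of the variance recursion at r = 1
        assert steady_state_gain(1.0, 1.0) == pytest.approx(0.6180, abs=1e-4)

    @pytest.mark.parametrize("r", [0.01, 0.1, 1.0, 10.0, 100.0])
    def test_matches_iterated_variance_recursion(self, r):
        assert steady_state_gain(r, 1.0) == pytest.approx(iterated_gain(r, 1.0), abs=1e-6)

    def test_strictly_increasing_in_noise_ratio(self):
        rs = np.geomspace(1e-3, 1e3, 31)
        ks = [steady_state_gain(r, 1.0) for r in rs]
        assert np.all(np.diff(ks) > 0)
        assert all(0.0 < k < 1.0 for k in ks)

    def test_degenerate_when_both_variances_vanish(self):
        with pytest.raises(DegenerateModelError):
            steady_state_gain(0.0, 0.0)


class TestSenseStep:
    def test_full_gain_copies_the_observation(self):
        x_hat, _ = sense_step(3.0, 0.0, X=12.5, Y=0.0, intended_a=0.0, k_x=1.0, k_y=0.0)
        assert x_hat == 12.5

    def test_zero_gain_keeps_the_prediction(self):
        x_hat, _ = sense_step(5.0, 0.0, X=99.0, Y=0.0, intended_a=0.0, k_x=0.0, k_y=0.0)
        assert x_hat == 5.0

    def test_y_prediction_advances_by_intended_action(self):
        _, y_hat = sense_step(0.0, 2.0, X=0.0, Y=123.0, intended_a=0.5, k_x=0.0, k_y=0.0)
        assert y_hat == 2.5

    def test_gain_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigError):
            sense_step(0.0, 0.0, 0.0, 0.0, 0.0, k_x=1.5, k_y=0.0)

    def test_matches_grid_based_sequential_bayes(self):
        # random-walk prior, Gaussian likelihood; the constant-gain filter
        # initialized at the steady state must equal the exact posterior mean
        q, r = 1.0, 1.0
        rng = np.random.default_rng(0)
        truth = np.cumsum(rng.normal(0, np.sqrt(q), 50))
        obs = truth + rng.normal(0, np.sqrt(r), 50)
        k = steady_state_gain(q, r)
        est = np.empty(50)
        est[0] = obs[0]
        for t in range(1, 50):
            est[t], _ = sense_step(est[t - 1], 0.0, obs[t], 0.0, 0.0, k, 0.0)
        oracle = grid_posterior_means(
            obs, q, r, prior_mean=obs[0], prior_var=steady_state_prior_variance(q, r)
        )
        assert np.max(np.abs(est[5:] - oracle[5:])) < 1e-3


class TestPerceive:
    def test_no_interaction_returns_target_estimate(self):
        y_tilde, clipped = perceive(x_hat=37.0, y_hat=20.0, beta=0.0, d=0.0)
        assert y_tilde == pytest.approx(20.0)
        assert not clipped

    def test_vertical_background_induces_nothing(self):
        y_tilde, _ = perceive(x_hat=0.0, y_hat=20.0, beta=0.7, d=0.0)
        assert y_tilde == pytest.approx(20.0)

    def test_hand_computed_interaction(self):
        # sin(20) - 0.7*sin(30) = 0.34202 - 0.35 = -0.00798 -> asin = -0.457 deg
        y_tilde, _ = perceive(x_hat=30.0, y_hat=20.0, beta=0.7, d=0.0)
        assert y_tilde == pytest.approx(-0.457, abs=1e-3)

    def test_out_of_range_component_is_clipped_and_flagged(self):
        y_tilde, clipped = perceive(x_hat=-90.0, y_hat=80.0, beta=0.9, d=0.2)
        assert clipped
        assert y_tilde == pytest.approx(90.0)


class TestActStep:
    def test_no_error_no_velocity_no_action(self):
        v, a = act_step(0.0, error=0.0, b=0.375, c=0.3, dt=0.05)
        assert v == 0.0 and a == 0.0

    def test_lightly_damped_spring_overshoots_a_step(self):
        # closed-loop response to a 10 deg step error overshoots the goal
        u = _step_response(0.375, 0.008, 0.0, 10.0, 400, 0.05)
        assert u.max() > 10.0

    def test_spring_nulls_a_constant_error(self):
        # long-run closed loop converges to the goal for a stable pair
        u = _step_response(0.375, 0.5, 0.0, 10.0, 2000, 0.05)
        assert abs(u[-1] - 10.0) < 1e-2

    def test_velocity_decays_when_error_is_zero(self):
        v = 8.0
        history = [abs(v)]
        for _ in range(200):
            v, _ = act_step(v, 0.0, b=0.375, c=0.3, dt=0.05)
            history.append(abs(v))
        assert np.all(np.diff(history) <= 0)

    def test_divergent_velocity_raises_stability_error(self):
        with pytest.raises(StabilityError, match="b="):
            act_step(1e7, 1e7, b=20.0, c=0.0, dt=0.05)


class TestSimulateSession:
    def test_fixed_point_with_no_noise_and_no_interaction(self):
        p = BPParams(
            sigma_omega2=0, sigma_psi2=0, sigma_phi2=0, sigma_lambda2=0, beta=0.0
        )
        walk = gen_session_walk(WalkConfig(seed=3))
        rec = simulate_session(walk, p, seed=0)
        assert np.allclose(rec.y.values, p.goal)

    def test_zero_sensory_noise_estimates_equal_world_states(self):
        p = BPParams(sigma_omega2=0, sigma_psi2=0, sigma_phi2=0, sigma_lambda2=0)
        walk = gen_session_walk(WalkConfig(seed=3))
        rec = simulate_session(walk, p, seed=0)
        assert np.allclose(rec.truth["x_hat"].to_numpy(), walk.values)
        assert np.allclose(rec.truth["y_hat"].to_numpy(), rec.y.values)

    def test_nulling_slope_recovers_interaction_strength(self):
        # with a slowly drifting background the participant nulls the
        # percept almost statically, so sin(y) ~ beta * sin(x)
        cfg = WalkConfig(sigma_mu=0.3, range_lo=-1e8, range_hi=1e8, buffer=0.0, seed=42)
        walk = gen_random_walk(cfg)
        rec = simulate_session(walk, BPParams(), seed=7)
        x = rec.x.discard_initial(10.0)
        y = rec.y.discard_initial(10.0)
        slope = np.polyfit(np.sin(np.radians(x.values)), np.sin(np.radians(y.values)), 1)[0]
        assert slope == pytest.approx(0.71, abs=0.1)

    def test_seeded_simulation_is_bit_reproducible(self, default_params):
        walk = gen_session_walk(WalkConfig(seed=5))
        a = simulate_session(walk, default_params, seed=123)
        b = simulate_session(walk, default_params, seed=123)
        assert np.array_equal(a.y.values, b.y.values)
        assert a.truth.equals(b.truth)

    def test_adaptation_accumulator_reduces_percept(self):
        # constant rightward exposure: after 20 steps at 6 deg/s the sensed
        # horizontal component has lost q * 120 deg/s
        p = BPParams(q=1e-4)
        walk_vals = np.zeros(21)
        from contpsych.series import AngleSeries

        walk = AngleSeries(dt=0.05, values=walk_vals)
        # delta_t longer than the horizon: the agent never reacts, so the
        # target holds 90 deg and only the accumulator moves the percept
        rec = simulate_session(walk, p.replace(sigma_omega2=0, sigma_psi2=0,
                                               sigma_lambda2=0, beta=0.0, goal=90.0,
                                               delta_t=2.0),
                               seed=0, y0=90.0)
        yt = rec.truth["y_tilde"].to_numpy()
        # percept at step t reflects accumulated exposure over steps < t
        expected = np.degrees(np.arcsin(1.0 - 1e-4 * 6.0 * 20 / 6.0))
        assert yt[20] == pytest.approx(expected, abs=1e-9)


class TestSimulateTraining:
    def test_unstable_lagged_spring_raises(self):
        # printed spring pairs are unstable in closed loop with the default
        # reaction lag: the guard must fire rather than emit garbage
        from contpsych import gen_blob_walk

        blob = gen_blob_walk(duration=600.0, seed=1)
        p = BPParams(
            sigma_phi2=0, sigma_psi2=0, sigma_lambda2=0, b=0.375, c=0.008, delta_t=0.4
        )
        with pytest.raises(StabilityError):
            simulate_training(blob, p, seed=0)

    def test_noiseless_training_is_deterministic(self):
        from contpsych import gen_blob_walk

        blob = gen_blob_walk(seed=4)
        p = BPParams(sigma_phi2=0, sigma_psi2=0, sigma_lambda2=0)
        a = simulate_training(blob, p, seed=0)
        b = simulate_training(blob, p, seed=99)
        assert np.array_equal(a.y.values, b.y.values)
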