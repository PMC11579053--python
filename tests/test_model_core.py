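"""Model core: Kalman filtering, activity dynamics, respiratory state,
readout and the composed forward model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from respercept import (
    ModelParams,
    activity_trajectory,
    forward_model,
    kalman_filter,
    readout,
    respiratory_state,
    steady_state_gain,
)

from conftest import grid_bayes_filter, riccati_fixed_point_gain

RHO_GRID = np.logspace(-3, 4, 15)


def make_params(**kw) -> ModelParams:
    base = dict(rho=1.0, w_c=1.0, activity=0.0, gain=1.0, offset=0.0)
    base.update(kw)
    return ModelParams(**base)


class TestSteadyStateGain:
    def test_matches_riccati_iteration(self):
        for rho in RHO_GRID:
            assert steady_state_gain(rho) == pytest.approx(
                riccati_fixed_point_gain(rho), abs=1e-10
            )

    def test_known_value_rho_2(self):
        # M = (1 + sqrt(9))/2 = 2, K = 2/(2+2)
        assert steady_state_gain(2.0) == pytest.approx(0.5, abs=1e-14)

    def test_limits(self):
        assert steady_state_gain(1e-12) == pytest.approx(1.0, abs=1e-5)
        assert steady_state_gain(1e6) < 1e-2  # ~1/sqrt(rho)

    def test_strictly_decreasing_in_rho(self):
        gains = [steady_state_gain(r) for r in RHO_GRID]
        assert np.all(np.diff(gains) < 0)

    def test_rejects_nonpositive_rho(self):
        with pytest.raises(ValueError):
            steady_state_gain(0.0)
        with pytest.raises(ValueError):
            steady_state_gain(-1.0)


class TestKalmanFilter:
    def test_constant_observations_zero_innovation(self):
        y = np.full(20, 5.3)
        c_hat, kgain = kalman_filter(y, rho=2.0)
        np.testing.assert_allclose(c_hat, 5.3, rtol=0, atol=1e-12)
        assert np.all((kgain > 0) & (kgain <= 1))

    def test_perfect_sensor_tracks_observations(self):
        y = 5.0 + np.sin(np.linspace(0, 3, 36))
        c_hat, _ = kalman_filter(y, rho=1e-10)
        np.testing.assert_allclose(c_hat, y, atol=1e-6)

    @pytest.mark.parametrize("rho", [0.1, 1.0, 5.0, 10.0])
    def test_matches_grid_bayes_filter(self, rho):
        """Posterior means agree with a brute-force discretized Bayesian
        filter to < 1e-3 % CO2 on a 36-step ramp."""
        y = np.linspace(5.2, 7.5, 36)
        c_hat, _ = kalman_filter(y, rho=rho, init_var=4.0)
        oracle = grid_bayes_filter(y, rho, init_mean=y[0], init_var=4.0)
        assert np.max(np.abs(c_hat - oracle)) < 1e-3

    @pytest.mark.parametrize("rho", [1e-3, 1.0, 1e4])
    def test_variance_recursion_converges_to_fixed_point(self, rho):
        """The iterated Riccati variance reaches the closed-form fixed
        point; convergence is geometric at rate (1 - K_ss)^2 per step, so
        large rho needs proportionally more steps."""
        k_ss = steady_state_gain(rho)
        m_ss = 0.5 * (1 + np.sqrt(1 + 4 * rho))
        p_ss = (1 - k_ss) * m_ss
        n_steps = max(200, int(30.0 / k_ss))
        p = 1e3
        for _ in range(n_steps):
            m = p + 1.0
            k = m / (m + rho)
            p = (1.0 - k) * m
        assert abs(p - p_ss) <= 1e-10
        # the filter's reported gains settle at the same fixed point
        _, kgain = kalman_filter(np.full(n_steps, 5.0), rho=rho)
        assert kgain[-1] == pytest.approx(k_ss, abs=1e-10)

    def test_variance_converges_within_200_steps_moderate_rho(self):
        for rho in [1e-3, 0.1, 1.0, 10.0, 100.0]:
            k_ss = steady_state_gain(rho)
            m_ss = 0.5 * (1 + np.sqrt(1 + 4 * rho))
            p = 1e3
            for _ in range(200):
                m = p + 1.0
                k = m / (m + rho)
                p = (1.0 - k) * m
            assert abs(p - (1 - k_ss) * m_ss) <= 1e-10

    def test_diffuse_start_first_estimate_is_first_observation(self):
        y = np.array([6.1, 5.0, 5.0])
        c_hat, _ = kalman_filter(y, rho=10.0)
        assert c_hat[0] == pytest.approx(6.1, abs=1e-3)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kalman_filter([], rho=1.0)
        with pytest.raises(ValueError):
            kalman_filter([5.0, np.nan], rho=1.0)
        with pytest.raises(ValueError):
            kalman_filter([5.0], rho=-1.0)


class TestActivityTrajectory:
    def test_matches_closed_form_and_recursion(self):
        a = activity_trajectory(1.0, tau_a=40.0, n_bins=36, bin_s=10.0)
        t = np.arange(36)
        np.testing.assert_array_equal(a, 1.0 * (1 - (1 - 10 / 40) ** t))
        # independent oracle: step the relaxation recursion
        rec = np.empty(36)
        val = 0.0
        for i in range(36):
            rec[i] = val
            val = val + (10.0 / 40.0) * (1.0 - val)
        np.testing.assert_allclose(a, rec, atol=1e-12)

    def test_saturates_after_two_minutes(self):
        a = activity_trajectory(1.0, tau_a=40.0, n_bins=36, bin_s=10.0)
        assert a[12] == pytest.approx(1 - 0.75**12, abs=1e-12)
        assert a[12] >= 0.95

    def test_zero_context_and_mirror_symmetry(self):
        assert np.all(activity_trajectory(0.0, 40.0, 36) == 0)
        up = activity_trajectory(1.0, 40.0, 36)
        down = activity_trajectory(-1.0, 40.0, 36)
        np.testing.assert_array_equal(down, -up)

    def test_monotone_toward_context_level(self):
        a = activity_trajectory(7.0, tau_a=50.0, n_bins=40)
        assert np.all(np.diff(a) > 0)
        assert a[-1] < 7.0

    def test_overshoot_warning(self):
        with pytest.warns(UserWarning, match="overshoot"):
            activity_trajectory(1.0, tau_a=5.0, n_bins=4, bin_s=10.0)


class TestRespiratoryState:
    def test_no_drive_gives_zero_state(self):
        p = make_params(w_c=0.0, activity=0.0)
        c_hat = np.full(10, 6.0)
        a = np.zeros(10)
        assert np.all(respiratory_state(c_hat, a, p) == 0)

    def test_memoryless_is_pointwise(self):
        p = make_params(w_c=1.5, activity=0.0)
        c_hat = np.array([5.0, 6.0, 5.5, 7.0])
        x = respiratory_state(c_hat, np.zeros(4), p, variant="no_memory")
        np.testing.assert_allclose(x, 1.5 * (c_hat - 5.0), atol=1e-12)

    def test_constant_input_geometric_limit(self):
        """Constant unit CO2 deviation with alpha = 0.8 converges to the
        geometric-series limit 1/(1 - alpha) = 5."""
        p = make_params(w_c=1.0, activity=0.0, alpha=0.8)
        c_hat = np.full(36, 6.0)  # c_ref + 1
        x = respiratory_state(c_hat, np.zeros(36), p)
        assert abs(x[30] - 5.0) / 5.0 < 1e-3

    def test_no_memory_equals_full_recursion_with_alpha_zero(self):
        rng = np.random.default_rng(0)
        c_hat = 5.0 + rng.normal(0, 1, 36)
        a = activity_trajectory(10.0, 40.0, 36)
        p = make_params(w_c=2.0, activity=10.0)
        x_nm = respiratory_state(c_hat, a, p, variant="no_memory")
        p0 = make_params(w_c=2.0, activity=10.0, alpha=0.0)
        x_full_a0 = respiratory_state(c_hat, a, p0, variant="full")
        np.testing.assert_allclose(x_nm, x_full_a0, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            respiratory_state(np.ones(5), np.ones(4), make_params())


class TestReadout:
    @pytest.mark.parametrize(
        "gain,offset,x,expected",
        [(1.0, 0.0, 50.0, 50.0), (1.0, 0.0, 200.0, 100.0), (1.0, 0.0, -5.0, 0.0)],
    )
    def test_affine_and_saturating(self, gain, offset, x, expected):
        assert readout(np.array([x]), gain, offset)[0] == expected

    def test_zero_gain_is_constant_offset(self):
        x = np.linspace(-100, 100, 7)
        np.testing.assert_array_equal(readout(x, 0.0, 130.0), 100.0)
        np.testing.assert_array_equal(readout(x, 0.0, 40.0), 40.0)

    @given(
        gain=st.floats(0, 50),
        offset=st.floats(-100, 100),
        xval=st.floats(-1e3, 1e3),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_always_within_rating_scale(self, gain, offset, xval):
        b = readout(np.array([xval]), gain, offset)
        assert 0.0 <= b[0] <= 100.0


class TestForwardModel:
    def test_no_drive_predicts_clipped_offset(self):
        etco2 = np.linspace(5, 7, 36)
        p = make_params(w_c=0.0, activity=0.0, offset=42.0)
        traj = forward_model(etco2, p)
        np.testing.assert_array_equal(traj.b_pred, 42.0)

    def test_full_equals_no_activity_when_context_is_zero(self):
        etco2 = np.linspace(5.2, 7.5, 36)
        p = make_params(rho=3.0, w_c=2.0, activity=0.0, gain=1.5, offset=3.0)
        t1 = forward_model(etco2, p, "full")
        t2 = forward_model(etco2, p, "no_activity")
        np.testing.assert_array_equal(t1.b_pred, t2.b_pred)

    def test_deterministic_bit_identical(self):
        etco2 = np.linspace(5.2, 7.5, 36)
        p = make_params(rho=3.0, w_c=2.0, activity=10.0, gain=1.5, offset=3.0)
        a = forward_model(etco2, p)
        b = forward_model(etco2, p)
        for f in ("c_hat", "kgain", "a", "x", "b_pred"):
            np.testing.assert_array_equal(getattr(a, f), getattr(b, f))

    def test_persistent_parameters_decouple_rating_from_co2(self):
        """An unreliable CO2 sensor plus strong activity context keeps the
        predicted rating high through recovery even though CO2 has
        returned to baseline."""
        from respercept import Protocol, generate_co2_trace, get_profile

        prof = get_profile("persistent", co2_noise_sd_pct=0.0)
        etco2 = generate_co2_trace(prof, Protocol())
        traj = forward_model(etco2, prof.params, prof.variant)
        last_60s = traj.b_pred[-6:]
        assert last_60s.mean() >= 0.5 * traj.b_pred.max()
        assert np.all(np.abs(etco2[-6:] - prof.baseline_pct) < 0.3)

    def test_output_lengths_and_bounds(self):
        etco2 = np.linspace(5.2, 7.5, 36)
        p = make_params(rho=0.5, w_c=5.0, activity=50.0, gain=10.0)
        traj = forward_model(etco2, p)
        assert len(traj) == 36
        for f in ("c_hat", "kgain", "a", "x"):
            assert getattr(traj, f).shape == (36,)
        assert np.all((traj.b_pred >= 0) & (traj.b_pred <= 100))
        assert np.all((traj.kgain > 0) & (traj.kgain <= 1))

    def test_rejects_linear_regression_variant(self):
        with pytest.raises(ValueError):
            forward_model(np.ones(5), make_params(), "linear_regression")
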