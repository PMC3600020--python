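import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _reference import rk4_fixed_step
from spgait.errors import InvalidParameterError, InvalidValueError
from spgait.oscillator import (
    DriveSignals,
    OscillatorParameters,
    OscillatorState,
    default_initial_state,
    input_signal,
    rectify,
    simulate,
    state_derivative,
)


def constant_drives(F_val, HA_val, duration=5.0, rate=200.0):
    t = np.arange(0.0, duration, 1.0 / rate)
    return DriveSignals(t, np.full_like(t, F_val), np.full_like(t, HA_val))


def decoupled_params(**overrides):
    """Neuron 1 driven by constant s = m1*p; neuron 2 silent."""
    base = dict(
        a_self=0.0, a_mut=-2.0, b1=0.0, b2=0.0, T1=1.0, T2=1.0,
        m1=1.0, m2=0.0, n1=0.0, n2=0.0, w1=0.0, w2=0.0, v1=0.0, v2=0.0,
        r1=10.0, r2=10.0,
    )
    base.update(overrides)
    return OscillatorParameters(**base)


class TestRectify:
    @pytest.mark.parametrize("x,expected", [(-0.5, 0.0), (0.0, 0.0), (0.3, 0.3)])
    def test_clamps_negative_passes_positive(self, x, expected):
        assert rectify(x) == expected

    def test_idempotent_on_arrays(self):
        x = np.array([-1.0, 0.0, 2.5])
        once = rectify(x)
        assert np.array_equal(rectify(once), once)
        assert np.all(once >= 0)

    @pytest.mark.parametrize("bad", [np.nan, np.inf])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(InvalidValueError):
            rectify(bad)


class TestInputSignal:
    def test_zero_weights_give_zero(self):
        p = decoupled_params(m1=0.0)
        assert input_signal(1.2, -3.0, 0.7, 9.9, p, 1) == 0.0

    def test_single_term_passthrough(self):
        p = decoupled_params(m1=1.0)
        assert input_signal(1.2, 0.0, 0.0, 0.0, p, 1) == pytest.approx(1.2)

    def test_hand_evaluated_linear_form(self):
        p = decoupled_params(m1=2.0, n1=0.5, w1=-1.0, v1=0.0)
        s = input_signal(1.0, 2.0, 0.4, 3.0, p, 1)
        assert s == pytest.approx(2.0 * 1.0 + 0.5 * 2.0 - 1.0 * 0.4)  # = 2.6

    def test_bad_neuron_index(self):
        with pytest.raises(InvalidParameterError):
            input_signal(0, 0, 0, 0, decoupled_params(), 3)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        p=st.floats(-5, 5), pd=st.floats(-5, 5),
        q=st.floats(-5, 5), qd=st.floats(-5, 5),
    )
    def test_linearity_in_drives(self, p, pd, q, qd):
        params = decoupled_params(m1=2.0, n1=0.5, w1=-1.0, v1=0.3)
        s1 = input_signal(p, pd, q, qd, params, 1)
        s2 = input_signal(2 * p, 2 * pd, 2 * q, 2 * qd, params, 1)
        assert s2 == pytest.approx(2 * s1, abs=1e-12)


class TestStateDerivative:
    def test_origin_fixed_point_with_zero_drive(self):
        p = decoupled_params(m1=0.0)
        d = state_derivative(OscillatorState(), 0.0, 0.0, p)
        assert np.array_equal(d, np.zeros(6))

    def test_mutual_inhibition_hand_value(self):
        # x1 = x2 = 1, a_mut = -2, a_self = 0, s = 0, b = 0 -> dx1 = -1 - 2 = -3
        p = decoupled_params(m1=0.0, a_mut=-2.0)
        st6 = OscillatorState(x1=1.0, x2=1.0)
        d = state_derivative(st6, 0.0, 0.0, p)
        assert d[0] == pytest.approx(-3.0)
        assert d[1] == pytest.approx(-3.0)

    def test_adaptation_and_smoothing_terms(self):
        p = decoupled_params(m1=0.0, b1=2.0, T1=0.5, r1=4.0, r2=8.0)
        st6 = OscillatorState(x1=1.0, f1=0.5, p=0.25, q=0.5)
        d = state_derivative(st6, 1.0, 0.0, p)
        assert d[0] == pytest.approx(-1.0 - 2.0 * 0.5)  # -x1 - b1*f1
        assert d[2] == pytest.approx((1.0 - 0.5) / 0.5)  # (y1 - f1)/T1
        assert d[4] == pytest.approx(4.0 * (1.0 - 0.25))  # r1*(F - p)
        assert d[5] == pytest.approx(8.0 * (0.0 - 0.5))  # r2*(HA - q)

    def test_invalid_time_constant_rejected_at_construction(self):
        with pytest.raises(InvalidParameterError):
            decoupled_params(T1=0.0)
        with pytest.raises(InvalidParameterError):
            decoupled_params(r1=0.0)
        with pytest.raises(InvalidParameterError):
            decoupled_params(a_mut=0.5)


class TestSimulate:
    def test_zero_drive_invariance(self):
        """s = 0 and zero initial state stays identically at the origin."""
        p = decoupled_params(m1=0.0)
        drives = constant_drives(0.0, 0.0)
        out = simulate(p, drives, OscillatorState())
        assert np.array_equal(out.state_trajectory, np.zeros_like(out.state_trajectory))

    def test_closed_form_decoupled_exponential(self):
        """a = 0, b = 0, constant s: x(t) = s + (x0 - s) e^(-t)."""
        p = decoupled_params()
        drives = constant_drives(1.0, 0.0)
        init = OscillatorState(p=1.0)  # p starts at F so s = 1 throughout
        out = simulate(p, drives, init)
        t = drives.timebase
        x_ref = 1.0 + (0.0 - 1.0) * np.exp(-t)
        err = np.max(np.abs(out.state_trajectory[:, 0] - x_ref))
        assert err < 1e-6
        # spot value at t = 1 s
        i = np.argmin(np.abs(t - 1.0))
        assert out.y1[i] == pytest.approx(0.63212, abs=1e-5)

    def test_no_adaptation_settles_to_constant(self):
        """b = 0 with constant drive: output rises then stays constant."""
        p = decoupled_params()
        drives = constant_drives(1.0, 0.0, duration=15.0)
        out = simulate(p, drives, OscillatorState(p=1.0))
        t = drives.timebase
        last = t >= t[-1] - 1.0
        dy = np.gradient(out.y1[last], t[last])
        assert out.y1[-1] > 0.99  # rose towards s = 1
        assert np.max(np.abs(dy)) < 1e-4 * np.max(out.y1)

    def test_outputs_nonnegative_and_rectified(self, truth_params, gait_drives):
        out = simulate(truth_params, gait_drives)
        assert np.all(out.y1 >= 0)
        assert np.all(out.y2 >= 0)
        assert np.array_equal(out.y1, np.maximum(0.0, out.state_trajectory[:, 0]))

    def test_smoothed_drives_stay_within_input_range(self, truth_params, gait_drives):
        """First-order lags cannot overshoot the range of their inputs."""
        out = simulate(truth_params, gait_drives, default_initial_state(gait_drives))
        p_traj = out.state_trajectory[:, 4]
        q_traj = out.state_trajectory[:, 5]
        tol = 1e-9
        assert p_traj.min() >= gait_drives.F.min() - tol
        assert p_traj.max() <= gait_drives.F.max() + tol
        assert q_traj.min() >= gait_drives.HA.min() - tol
        assert q_traj.max() <= gait_drives.HA.max() + tol

    def test_matches_fixed_step_reference(self, truth_params, gait_drives):
        """Adaptive integration agrees with an independent RK4 at dt = 1e-4."""
        init = default_initial_state(gait_drives)
        out = simulate(truth_params, gait_drives, init)
        ref = rk4_fixed_step(
            truth_params.to_dict(),
            gait_drives.timebase,
            gait_drives.F,
            gait_drives.HA,
            init.to_array(),
            dt=1e-4,
        )
        assert np.max(np.abs(out.state_trajectory - ref)) < 1e-5


class TestDriveSignals:
    def test_rejects_negative_force(self):
        t = np.arange(0, 1, 0.01)
        with pytest.raises(InvalidValueError):
            DriveSignals(t, np.full_like(t, -0.1), np.zeros_like(t))

    def test_rejects_nonuniform_timebase(self):
        t = np.array([0.0, 0.1, 0.3, 0.35])
        with pytest.raises(InvalidValueError):
            DriveSignals(t, np.zeros_like(t), np.zeros_like(t))


class TestParameterSerialization:
    def test_json_round_trip(self, truth_params):
        restored = OscillatorParameters.from_json(truth_params.to_json())
        assert restored == truth_params

    def test_array_round_trip_preserves_order(self, truth_params):
        arr = truth_params.to_array()
        assert OscillatorParameters.from_array(arr) == truth_params
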