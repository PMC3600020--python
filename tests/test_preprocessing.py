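import numpy as np
import pytest

from spgait.errors import (
    AlignmentError,
    InsufficientDataError,
    InsufficientStridesError,
    InvalidParameterError,
)
from spgait.preprocessing import (
    condition_emg,
    detect_strides,
    normalize_force,
    preprocess_trial,
    resample_common,
)
from spgait.synthetic import SyntheticConfig, generate_trial


def square_force(stance_frac=0.65, cycle_s=1.1, n_cycles=6, rate=200.0, peak=1.2):
    """Rectangular contact pattern with known stance fraction."""
    t = np.arange(0.0, n_cycles * cycle_s + 0.3, 1.0 / rate)
    phase = (t - 0.1) / cycle_s
    in_cycle = (phase >= 0) & (phase < n_cycles)
    F = np.where(in_cycle & ((phase % 1.0) < stance_frac), peak, 0.0)
    return t, F


class TestConditionEmg:
    def test_constant_series_maps_to_zero(self):
        env = condition_emg(np.full(4000, 3.7), rate=2000.0)
        assert np.max(np.abs(env)) < 1e-9

    def test_nonnegative_output(self):
        rng = np.random.default_rng(0)
        env = condition_emg(rng.standard_normal(5000), rate=2000.0)
        assert np.all(env >= 0)

    def test_low_frequency_envelope_kept_high_frequency_ripple_removed(self):
        # A slow envelope modulating a fast carrier should survive; the
        # rectified carrier ripple (>= twice the carrier frequency, far above
        # the 40 Hz cutoff) should be flattened to the rectified mean.
        rate = 2000.0
        t = np.arange(0, 4, 1 / rate)
        slow = np.sin(2 * np.pi * 10 * t)  # 10 Hz, passes
        fast = np.sin(2 * np.pi * 450 * t)  # 450 Hz carrier
        env_slow = condition_emg(slow, rate)
        env_fast = condition_emg(fast, rate)
        mid = slice(int(0.5 * rate), int(3.5 * rate))
        # |sin| of a passed tone still varies strongly (its 20 Hz harmonic
        # is inside the band); the 450 Hz tone's ripple (900 Hz) is not.
        assert np.std(env_slow[mid]) > 10 * np.std(env_fast[mid])
        # the surviving fast-tone envelope is the rectified mean, 2/pi
        assert np.mean(env_fast[mid]) == pytest.approx(2 / np.pi, rel=0.02)

    def test_causal_mode_differs_but_stays_nonnegative(self):
        rng = np.random.default_rng(1)
        raw = rng.standard_normal(4000)
        zp = condition_emg(raw, 2000.0, zero_phase=True)
        causal = condition_emg(raw, 2000.0, zero_phase=False)
        assert np.all(causal >= 0)
        assert not np.allclose(zp, causal)

    def test_too_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            condition_emg(np.ones(10), rate=2000.0)

    def test_rate_below_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            condition_emg(np.ones(1000), rate=60.0)


class TestNormalizeForce:
    @pytest.mark.parametrize(
        "force,weight,expected",
        [(764.0, 764.0, 1.0), (0.0, 764.0, 0.0), (955.0, 764.0, 1.25)],
    )
    def test_division_by_body_weight(self, force, weight, expected):
        assert normalize_force(np.array([force]), weight)[0] == pytest.approx(expected)

    def test_negative_readings_clamped(self):
        out = normalize_force(np.array([-5.0, 10.0]), 100.0)
        assert out[0] == 0.0 and out[1] == pytest.approx(0.1)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(InvalidParameterError):
            normalize_force(np.ones(3), 0.0)


class TestResampleCommon:
    def test_identity_at_shared_knots(self):
        t = np.arange(0, 1, 0.01)
        v = np.sin(t * 7)
        tb, res = resample_common({"a": (t, v)}, rate=100.0)
        assert np.allclose(res["a"], np.interp(tb, t, v))
        assert np.allclose(res["a"][: v.size], v, atol=1e-12)

    def test_linear_ramp_exact_at_midpoints(self):
        t = np.arange(0, 2, 0.01)  # 100 Hz ramp HA(t) = t
        tb, res = resample_common({"ha": (t, t)}, rate=200.0)
        assert np.allclose(res["ha"], tb, atol=1e-12)

    def test_burst_envelope_round_trip(self):
        # a 2000 Hz burst envelope (energy well below 40 Hz) survives a
        # 200 Hz round trip with <1% change in peak value
        from spgait.synthetic import SyntheticConfig, _template_envelopes

        cfg = SyntheticConfig()
        spec = cfg.conditions["4.0"]
        t = np.arange(0, 4, 1 / 2000)
        sol, _ = _template_envelopes(cfg, spec, t, 0.3, np.random.default_rng(0))
        tb, down = resample_common({"s": (t, sol)}, rate=200.0)
        _, up = resample_common({"s": (tb, down["s"])}, rate=2000.0)
        n = up["s"].size
        assert abs(up["s"].max() - sol[:n].max()) / sol.max() < 0.01
        assert np.max(np.abs(up["s"] - sol[:n])) / sol.max() < 0.01

    def test_disjoint_channels_rejected(self):
        with pytest.raises(AlignmentError):
            resample_common(
                {
                    "a": (np.array([0.0, 1.0]), np.zeros(2)),
                    "b": (np.array([2.0, 3.0]), np.zeros(2)),
                }
            )


class TestDetectStrides:
    def test_recovers_known_stance_fraction(self):
        t, F = square_force(stance_frac=0.65, cycle_s=1.1, n_cycles=6)
        strides = detect_strides(F, t)
        assert len(strides) == 5  # 6 contacts -> 5 complete strides
        dt = t[1] - t[0]
        for ev in strides:
            frac = (ev.toe_off - ev.heel_strike) / ev.duration
            assert abs(frac - 0.65) <= (dt / 1.1) + 1e-9

    def test_stance_plus_swing_partitions_stride(self):
        t, F = square_force()
        for ev in detect_strides(F, t):
            swing = ev.next_heel_strike - ev.toe_off
            assert ev.stance_duration + swing == pytest.approx(ev.duration)

    def test_zero_force_rejected(self):
        t = np.arange(0, 5, 0.005)
        with pytest.raises(InsufficientStridesError):
            detect_strides(np.zeros_like(t), t)

    def test_swing_baseline_noise_debounced(self):
        t, F = square_force()
        rng = np.random.default_rng(3)
        noisy = F + np.where(F == 0, rng.uniform(-0.01, 0.01, F.size), 0.0)
        noisy = np.maximum(0.0, noisy)
        assert len(detect_strides(noisy, t)) == len(detect_strides(F, t))

    def test_short_contact_spike_removed(self):
        t, F = square_force()
        spike = F.copy()
        i = np.flatnonzero(F == 0)[10]
        spike[i : i + 3] = 0.5  # 15 ms blip, under the 50 ms debounce
        assert len(detect_strides(spike, t)) == len(detect_strides(F, t))


@pytest.fixture(scope="module")
def raw_trial():
    cfg = SyntheticConfig(emg_mode="template", noise_sd=0.02, seed=9)
    return generate_trial(cfg, "4.0", seed=9)


class TestPreprocessTrial:

    def test_full_chain_recovers_generator_structure(self, raw_trial):
        rec, truth = raw_trial
        trial = preprocess_trial(rec)
        assert trial.n_strides == len(truth.stride_events)
        dt = 1.0 / trial.rate
        stance_true = truth.condition_effects["stance_fraction"]
        period = truth.condition_effects["stride_s"]
        for ev in trial.stride_events:
            frac = ev.stance_duration / ev.duration
            assert abs(frac - stance_true) <= 2 * dt / period

    def test_outputs_nonnegative(self, raw_trial):
        rec, _ = raw_trial
        trial = preprocess_trial(rec)
        assert np.all(trial.emg_sol >= 0)
        assert np.all(trial.emg_ta >= 0)
        assert np.all(trial.F >= 0)
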