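import numpy as np
import pytest

from spgait.oscillator import DriveSignals, OscillatorParameters
from spgait.synthetic import (
    GROUND_TRUTH_PARAMS,
    SyntheticConfig,
    make_processed_trial,
)


@pytest.fixture(scope="session")
def truth_params() -> OscillatorParameters:
    return GROUND_TRUTH_PARAMS


@pytest.fixture(scope="session")
def gait_drives():
    """5 s of synthetic gait-like drives at 200 Hz (seeded)."""
    cfg = SyntheticConfig(seed=5)
    rng = np.random.default_rng(5)
    from spgait.synthetic import generate_force, generate_hip

    timebase = np.arange(0.0, 5.0, 1.0 / 200.0)
    _, F = generate_force(cfg, "4.0", rng, timebase)
    _, HA = generate_hip(cfg, "4.0", rng, timebase)
    return DriveSignals(timebase, F, HA)


@pytest.fixture(scope="session")
def oscillator_trial():
    """Noiseless oscillator-mode processed trial with its ground truth."""
    cfg = SyntheticConfig(emg_mode="oscillator", noise_sd=0.0)
    return make_processed_trial(cfg, "4.0", seed=7)


@pytest.fixture(scope="session")
def noisy_oscillator_trial():
    """Oscillator-mode trial with 10%-of-peak envelope noise."""
    cfg = SyntheticConfig(emg_mode="oscillator", noise_sd=0.10)
    return make_processed_trial(cfg, "4.0", seed=7)


@pytest.fixture(scope="session")
def template_trial():
    """Noiseless template-mode processed trial."""
    cfg = SyntheticConfig(emg_mode="template", noise_sd=0.0)
    return make_processed_trial(cfg, "4.0", seed=3)
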