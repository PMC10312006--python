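import numpy as np
import pytest

from pupilwave import PreprocessConfig, SimConfig


@pytest.fixture
def quiet_sim_cfg():
    """Noise-free, blink-free, reflex-free generator config."""
    return SimConfig(
        trial_length_s=60.0, phi=0.5, tonic_sd=0.0, noise_sd=0.0,
        blink_rate_hz=0.0, light_reflex_amp_mm=0.0, baseline_mm=4.0, seed=7,
    )


@pytest.fixture
def default_sim_cfg():
    return SimConfig(seed=11)


@pytest.fixture
def pp_cfg():
    return PreprocessConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
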