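import numpy as np
import pytest

from fixfrp import simulate
from fixfrp.simulate import SimConfig


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A quick moderate-size session: 60 fixations, defaults otherwise."""
    return SimConfig(n_fixations_per_trial=60, seed=11)


@pytest.fixture(scope="session")
def small_subject(small_config):
    """Layout, gaze stream, ground truth and recording for one small subject."""
    rng = np.random.default_rng(small_config.seed)
    return simulate.simulate_subject(small_config, rng)


@pytest.fixture(scope="session")
def highsnr_subject():
    """Reference high-SNR subject used by classification-level tests."""
    cfg = simulate.reference_high_snr_config(seed=21, n_fixations_per_trial=150)
    rng = np.random.default_rng(21)
    return cfg, simulate.simulate_subject(cfg, rng)
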