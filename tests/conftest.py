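import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from numtex import blur_norm, filters

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def k_high():
    """High-spatial-frequency LoG channel (sigma = 2 px)."""
    return filters.make_log_kernel(2.0)


@pytest.fixture(scope="session")
def k_low():
    """Low-spatial-frequency LoG channel (sigma = 8 px)."""
    return filters.make_log_kernel(8.0)


@pytest.fixture(scope="session")
def calibration(k_high):
    """Blur/log-energy quadratic calibrated on single-dot stimuli."""
    return blur_norm.calibrate_energy_poly(
        k_high, np.arange(2.5, 7.51, 0.625), np.random.default_rng(11),
        n_reps=8)
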