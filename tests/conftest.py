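import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from svispec import NoiseModel, simulate_task_spectra

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ZERO_NOISE = NoiseModel(pixel_sd=0.0, jitter=0.0, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_task5_zero_noise():
    """Task-5 adulteration series at zero noise, small frames for speed."""
    return simulate_task_spectra(5, seed=3, noise=ZERO_NOISE,
                                 frame_count=24, roi_size=6)


@pytest.fixture(scope="session")
def tiny_task1_zero_noise():
    """Full 15-brand design at zero noise, small frames for speed."""
    return simulate_task_spectra(1, seed=3, noise=ZERO_NOISE,
                                 frame_count=24, roi_size=6)
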