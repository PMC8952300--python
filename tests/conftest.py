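import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gaitharmonics import GaitSimConfig, load_model_library

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return load_model_library()


@pytest.fixture()
def clean_config():
    """Generator settings with every stochastic term switched off."""
    return GaitSimConfig(
        n_strides=10,
        pattern_sequence=(1,),
        stride_time_cv=0.0,
        noise_deg_sd=0.0,
        extra_harmonic_frac=0.0,
        gyro_noise_dps_sd=0.0,
        accel_noise_g_sd=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
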