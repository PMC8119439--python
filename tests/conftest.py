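import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    from pulmotrunk import PhantomParams

    return PhantomParams()


@pytest.fixture(scope="session")
def small_cohort(default_params):
    """32 default phantoms, enough for fast training smoke tests."""
    from pulmotrunk import generate_cohort

    return generate_cohort(default_params, 32, seed=42)


@pytest.fixture(scope="session")
def tiny_cohort():
    """16 small (32x32) phantoms for fast CLI / CV round trips."""
    from pulmotrunk import PhantomParams, generate_cohort

    params = PhantomParams(image_rows=32, image_cols=32, band_height_rows=(5, 9),
                           shift_jitter_rows=1)
    return generate_cohort(params, 16, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
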