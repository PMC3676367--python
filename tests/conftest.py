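import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import thermofield as tf

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def full_design():
    """The study layout: 192 genotypes x 2 replicates, 24 rows of 16 plots."""
    return tf.generate_layout(192, 2, 16, 8, seed=42)


@pytest.fixture(scope="session")
def small_design():
    """A small trial for fast simulations: 48 genotypes x 2 reps, 6 x 16."""
    return tf.generate_layout(48, 2, 16, 8, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
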