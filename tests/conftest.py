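import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from betacorr.core import TaskTiming
from betacorr.segmentation import prepare_pair
from betacorr.synthetic_data import GeneratorConfig, generate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def timing_t():
    return TaskTiming.monkey_t()


@pytest.fixture(scope="session")
def small_pair(timing_t):
    """A small two-direction null pair (no coupling, no locking), reused by
    tests that only need plausible task-structured data."""
    cfg = GeneratorConfig(n_trials_per_condition=10, directions=(1, 4))
    return generate_pair(cfg, timing_t, 0, np.random.SeedSequence(42))


@pytest.fixture(scope="session")
def small_prepared(small_pair):
    return prepare_pair(small_pair, 22.0, 5.0)
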