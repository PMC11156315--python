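import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_world():
    """A light landmark field for unit tests (same geometry, 10x fewer
    landmarks than the study map)."""
    from artnav.world import build_world

    return build_world(landmark_seed=7, n_landmarks=650)


@pytest.fixture(scope="session")
def default_world():
    from artnav.world import build_world

    return build_world(landmark_seed=7)
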