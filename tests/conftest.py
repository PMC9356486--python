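import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from camhip.shape_io import LandmarkScheme
from camhip.synthetic import OutlineParams, generate_outline


@pytest.fixture
def scheme() -> LandmarkScheme:
    return LandmarkScheme()


@pytest.fixture
def make_outline():
    """Factory for synthetic outlines; returns (outline, analytic alpha)."""

    def _make(**kwargs):
        return generate_outline(OutlineParams(**kwargs))

    return _make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
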