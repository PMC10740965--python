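import numpy as np
import pytest

from arcgait import AnthropometricProfile, ModelConstants


@pytest.fixture
def profile():
    """Cohort-typical geometry: leg 0.9 m, foot 0.25 m."""
    return AnthropometricProfile(L=0.9, f=0.25, r=0.05)


@pytest.fixture
def constants():
    return ModelConstants(g=9.81, xi=0.10)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
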