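import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from acrdyn import ModelParameters, PopulationState

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def reference_params() -> ModelParameters:
    """The reference parameter set: a=0.001, A=0.2, B=5, rho=0.5 with a
    moderately strong anti-CRISPR (phi=0.3, 1/gamma=1)."""
    return ModelParameters()


@pytest.fixture
def mixed_initial() -> PopulationState:
    """Sensitive hosts plus an equal 100:100 mix of the two phage types."""
    return PopulationState(W=1e3, V1=100.0, V2=100.0)


@pytest.fixture
def sample_times():
    return np.linspace(0.0, 30.0, 301)
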