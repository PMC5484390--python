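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

from lcachoice import ChoiceSet


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def canonical_inputs():
    """The worked three-alternative attribute vector used throughout."""
    return np.array([0.75, 0.5, 0.25])


def single_attribute_set(values) -> ChoiceSet:
    """A one-attribute choice set wrapping a plain value vector."""
    return ChoiceSet(values=np.asarray(values, dtype=float)[:, None], weights=[1.0])


@pytest.fixture(scope="session")
def two_by_two_set():
    """The worked 2-alternative, 2-attribute example set."""
    return ChoiceSet(values=[[0.8, 0.2], [0.4, 0.9]], weights=[0.03, 0.015])
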