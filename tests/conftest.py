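import pytest
from hypothesis import HealthCheck, settings

from dddfba.synthetic_data import (
    ToySpec, default_kinetics, parallel_route_model, toy_model,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def anaerobic_model():
    return toy_model()


@pytest.fixture(scope="session")
def aerobic_model():
    return toy_model(ToySpec(aerobic=True))


@pytest.fixture(scope="session")
def kinetics():
    return default_kinetics()


@pytest.fixture(scope="session")
def parallel_model():
    return parallel_route_model()


@pytest.fixture()
def fresh_toy_model():
    """Mutable copy for tests that change bounds destructively."""
    return toy_model()
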