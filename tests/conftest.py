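import pytest
from hypothesis import HealthCheck, settings

from meaburst import detect_all, make_fixture

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sync_fixture():
    """Synchronous-network scenario: voltage recording + ground truth."""
    return make_fixture("synchronous_network")


@pytest.fixture(scope="session")
def sync_trains(sync_fixture):
    """Spike trains detected from the synchronous fixture's voltage."""
    rec, _ = sync_fixture
    return detect_all(rec)


@pytest.fixture(scope="session")
def hyper_fixture():
    """Hyperexcitable-asynchronous scenario: voltage recording + ground truth."""
    return make_fixture("hyperexcitable_asynchronous")


@pytest.fixture(scope="session")
def hyper_trains(hyper_fixture):
    rec, _ = hyper_fixture
    return detect_all(rec)


@pytest.fixture(scope="session")
def silent_fixture():
    return make_fixture("silent")
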