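import pytest
from hypothesis import HealthCheck, settings

from prepmonitor.cohort_sim import SimulationConfig, fixture_suite, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_store_truth():
    """One mid-size simulated cohort shared across tests (fixed seed)."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def sim_store(sim_store_truth):
    return sim_store_truth[0]


@pytest.fixture(scope="session")
def fixtures():
    return fixture_suite()
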