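import pytest
from hypothesis import HealthCheck, settings

from allelesplice import pipeline as pl
from allelesplice.simulate import SimulationConfig, simulate_dataset

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A quick dataset for structural checks."""
    return simulate_dataset(SimulationConfig(n_events=300), seed=11)


@pytest.fixture(scope="session")
def small_result(small_dataset):
    return pl.run_divergence(small_dataset)


@pytest.fixture(scope="session")
def std_dataset():
    """The standard study-conditions dataset (generator defaults)."""
    return simulate_dataset(SimulationConfig(), seed=1)


@pytest.fixture(scope="session")
def std_result(std_dataset):
    return pl.run_divergence(std_dataset)
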