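import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from socagg.litter import AwenTable, TurnoverTable
from socagg.params import default_parameters
from socagg.synth import generate_dataset

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def turnover():
    return TurnoverTable.default()


@pytest.fixture(scope="session")
def awen():
    return AwenTable.default()


@pytest.fixture(scope="session")
def small_dataset():
    """200-plot landscape shared by the slower integration tests."""
    return generate_dataset(200, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
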