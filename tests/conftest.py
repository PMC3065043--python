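import pytest
from hypothesis import HealthCheck, settings

from nanocell import AdministrationSchedule, Grid, default_parameters

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def lung():
    return default_parameters("lung")


@pytest.fixture(scope="session")
def melanoma():
    return default_parameters("melanoma")


@pytest.fixture(scope="session")
def schedule():
    return AdministrationSchedule()


@pytest.fixture
def smoke_grid(lung):
    """Small grid for fast dynamical checks: 16^3 voxels, coarse spacing."""
    return Grid.for_params(lung, shape=(16, 16, 16), h=1.0)
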