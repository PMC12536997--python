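import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cholecea import CostEffectivenessModel, load_parameters  # noqa: E402


@pytest.fixture(scope="session")
def table1():
    """The packaged cholecystitis parameter table."""
    return load_parameters()


@pytest.fixture(scope="session")
def model(table1):
    return CostEffectivenessModel(table1)


@pytest.fixture(scope="session")
def basecase(model):
    return model.fit()
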