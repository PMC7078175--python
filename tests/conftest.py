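import pytest
from hypothesis import HealthCheck, settings

from shoredep import HabitatParams, PersistenceCurve, load_table1

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def beach(table1):
    return table1["beach"]


@pytest.fixture(scope="session")
def marsh(table1):
    return table1["marsh"]


@pytest.fixture(scope="session")
def ideal():
    """Perfect detection and persistence: the estimator becomes the identity."""
    return HabitatParams("ideal", 1.0, PersistenceCurve((1.0,) * 12))
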