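import pytest
from hypothesis import HealthCheck, settings

from labpi import fixture_table

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1():
    return fixture_table("table1")


@pytest.fixture(scope="session")
def table2():
    return fixture_table("table2")


@pytest.fixture(scope="session")
def table3():
    return fixture_table("table3")


@pytest.fixture(scope="session")
def table4():
    return fixture_table("table4")


@pytest.fixture(scope="session")
def table5():
    return fixture_table("table5")


@pytest.fixture(scope="session")
def table5_glucose(table5):
    return table5["glucose"]


@pytest.fixture(scope="session")
def table5_cholesterol(table5):
    return table5["cholesterol"]
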