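import pytest
from hypothesis import HealthCheck, settings

from archaeolipid import io as alio
from archaeolipid import registry as alreg
from archaeolipid import stats as alstats

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return alreg.default_registry()


@pytest.fixture(scope="session")
def table1():
    return alio.load_table1_fixture()


@pytest.fixture(scope="session")
def profiles(table1):
    return table1.profiles()


@pytest.fixture(scope="session")
def class_totals(profiles):
    return alstats.class_totals_table(profiles)
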