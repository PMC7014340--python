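import pytest
from hypothesis import HealthCheck, settings

from phosload.core_types import load_defaults
from phosload.synthetic import case_study

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def defaults():
    """(export-coefficient table, per-capita rates, OECD parameters)."""
    return load_defaults()


@pytest.fixture(scope="session")
def ec_table(defaults):
    return defaults[0]


@pytest.fixture(scope="session")
def rates(defaults):
    return defaults[1]


@pytest.fixture(scope="session")
def oecd(defaults):
    return defaults[2]


@pytest.fixture(scope="session")
def case_fixtures():
    """All six case-study fixtures, built once per session."""
    return {name: case_study(name) for name in
            ("heldale", "skene", "leven", "menteith", "strathclyde", "milton")}
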