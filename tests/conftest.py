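import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_compounds():
    from netpharm.fixtures import make_fixture_compounds

    return make_fixture_compounds()


@pytest.fixture(scope="session")
def fixture_interactions():
    from netpharm.fixtures import make_fixture_interactions

    return make_fixture_interactions()


@pytest.fixture(scope="session")
def fixture_ct_network(fixture_compounds, fixture_interactions):
    from netpharm.network import build_ct_network

    return build_ct_network(fixture_compounds, fixture_interactions)
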