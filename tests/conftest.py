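import pytest
from hypothesis import settings

import lymphrisk as lr

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Deterministic fixture bundle: 12-patient cohort, 2-region rates,
    placeholder dose-response config."""
    out = tmp_path_factory.mktemp("fixture")
    return lr.make_fixture_bundle(out)


@pytest.fixture(scope="session")
def cohort(bundle):
    return lr.read_cohort(bundle["cohort"])


@pytest.fixture(scope="session")
def regions(bundle):
    return lr.read_rate_tables(bundle["rates"])


@pytest.fixture(scope="session")
def us_rates(regions):
    return regions["united_states"]


@pytest.fixture(scope="session")
def cfg(bundle):
    return lr.load_config(bundle["config"])


@pytest.fixture(scope="session")
def four_region_rates():
    return lr.simulate_rate_tables(lr.RateSimSpec())
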