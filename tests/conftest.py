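import pytest
from hypothesis import settings

from bipolarcua import synthetic

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def suite():
    """The named fixture suite (base case + toys + stress cases)."""
    return synthetic.make_fixture_suite()


@pytest.fixture(scope="session")
def base_params(suite):
    return suite["tables12_base"]


@pytest.fixture(scope="session")
def zero_risk(suite):
    return suite["zero_risk"]


@pytest.fixture(scope="session")
def symmetric(suite):
    return suite["symmetric"]
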