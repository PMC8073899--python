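import pytest
from hypothesis import settings

from fcmsim.synthetic import mld_fixture

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mld():
    """The curated MLD toy fixture (network, protocol, profiles, drugs)."""
    return mld_fixture()
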