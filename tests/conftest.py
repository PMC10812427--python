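import pytest
from hypothesis import settings

from surfscreen.model import GOCatalog

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog() -> GOCatalog:
    return GOCatalog()
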