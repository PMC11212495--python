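import pytest

from ltrmnm import load_fixture


@pytest.fixture(scope="session")
def namibia():
    """The embedded Namibia 2019 worked-example bundle."""
    return load_fixture("namibia2019")
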