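import pytest

from aqpkit import io
from aqpkit.templates import default_templates


@pytest.fixture(scope="session")
def roster():
    return io.load_roster()


@pytest.fixture(scope="session")
def sdp_tables():
    return io.load_sdp_tables()


@pytest.fixture(scope="session")
def catalog():
    return io.load_cre_catalog()


@pytest.fixture(scope="session")
def presence_fixture():
    return io.load_presence_fixture()


@pytest.fixture(scope="session")
def templates():
    return default_templates()
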