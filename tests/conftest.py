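import pytest

from tolnet import make_fixture


@pytest.fixture
def star():
    return make_fixture("star_source")


@pytest.fixture
def looped_star():
    return make_fixture("looped_star")


@pytest.fixture
def cycle():
    return make_fixture("cycle_source")


@pytest.fixture
def chain():
    return make_fixture("chain_absorbing")


@pytest.fixture(scope="session")
def oral():
    return make_fixture("oral_tolerance")
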