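import pytest

import serplith as sp


@pytest.fixture(scope="session")
def constants():
    return sp.load_constants()


@pytest.fixture(scope="session")
def registry(constants):
    return sp.load_pathways(constants)


@pytest.fixture(scope="session")
def hakuba():
    return sp.load_site("hakuba")


@pytest.fixture(scope="session")
def cedars():
    return sp.load_site("cedars")


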