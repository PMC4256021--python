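import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from foldmaps.fixtures import naive_enumerate_walks
from foldmaps.lattice import enumerate_conformations


@pytest.fixture(scope="session")
def inv8():
    return enumerate_conformations(8)


@pytest.fixture(scope="session")
def inv10():
    return enumerate_conformations(10)


@pytest.fixture(scope="session")
def walks8():
    return naive_enumerate_walks(8)
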