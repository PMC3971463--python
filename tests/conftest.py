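import pytest

from shm import BoundarySet, FrequencyTable, ResponseScale
from shm.fixtures import load_fixture


@pytest.fixture
def pols2008() -> FrequencyTable:
    return load_fixture("pols2008")


@pytest.fixture
def eb2008() -> FrequencyTable:
    return load_fixture("eb2008")


@pytest.fixture
def pols_judges() -> BoundarySet:
    return load_fixture("pols_judges")


@pytest.fixture
def eb_judges() -> BoundarySet:
    return load_fixture("eb_judges")


@pytest.fixture
def scale5() -> ResponseScale:
    return ResponseScale("v5", "verbal", ("a", "b", "c", "d", "e"))


@pytest.fixture
def scale4() -> ResponseScale:
    return ResponseScale("v4", "verbal", ("w", "x", "y", "z"))


@pytest.fixture
def scale3() -> ResponseScale:
    return ResponseScale("v3", "verbal", ("lo", "mid", "hi"))
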