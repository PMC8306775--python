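import pytest

from cftrmap.fixtures import packaged_cftr_fixture
from cftrmap.model import Layer


@pytest.fixture(scope="session")
def cftr_fixture():
    return packaged_cftr_fixture()


@pytest.fixture(scope="session")
def core_entities(cftr_fixture):
    return [i for i in cftr_fixture.dataset.interactors if i.layer == Layer.CORE]


@pytest.fixture(scope="session")
def coarse_entities(cftr_fixture):
    return [i for i in cftr_fixture.dataset.interactors if i.layer == Layer.COARSE]
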