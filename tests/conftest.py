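import numpy as np
import pytest

from aarscreen import synthetic_data as S


@pytest.fixture(scope="session")
def ancestors():
    return S.lineage_ancestors()


@pytest.fixture(scope="session")
def reference_set():
    return S.default_reference_set()


@pytest.fixture(scope="session")
def architecture_refs():
    return S.default_architecture_refs()


@pytest.fixture
def rng():
    return np.random.default_rng(20170221)


def random_protein(rng, n, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet), n))
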