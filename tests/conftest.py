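import numpy as np
import pytest

from plantsurvey import simdata
from plantsurvey.organelle_filter import build_organelle_index


@pytest.fixture(scope="session")
def organelle_30k() -> str:
    return simdata.make_organelle_genome(30_000, seed=7)


@pytest.fixture(scope="session")
def organelle_index_30k(organelle_30k):
    return build_organelle_index([("org0", organelle_30k)], read_len=140)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
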