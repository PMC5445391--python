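import numpy as np
import pytest
from hypothesis import settings

from saeppi.sequence_codec import (
    AMINO_ACIDS,
    default_cluster_map,
    default_descriptor_table,
)

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def descriptor_table():
    return default_descriptor_table()


@pytest.fixture(scope="session")
def cluster_map():
    return default_cluster_map()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n):
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


@pytest.fixture
def make_seq(rng):
    return lambda n: random_seq(rng, n)
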