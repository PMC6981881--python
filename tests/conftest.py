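import numpy as np
import pytest

from cryptarget import MatureMiRNA, default_parameters
from cryptarget.datasets import (
    PUBLISHED_MIRNA_SEQ,
    load_published_duplexes,
    load_published_trans,
)


@pytest.fixture(scope="session")
def mirna():
    return MatureMiRNA("novel-m3234-5p", PUBLISHED_MIRNA_SEQ)


@pytest.fixture(scope="session")
def published_duplexes():
    return load_published_duplexes()


@pytest.fixture(scope="session")
def published_trans():
    return load_published_trans()


@pytest.fixture(scope="session")
def nn_params():
    return default_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260917)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))
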