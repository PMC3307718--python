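import numpy as np
import pytest

import bfmprotein as b


@pytest.fixture(scope="session")
def h2ax():
    return b.h2ax_sequence()


@pytest.fixture(scope="session")
def mj_contact():
    """Packaged table, raw contact variant (all-attractive)."""
    return b.load_contact_matrix(variant="contact")


@pytest.fixture(scope="session")
def mj_mixing():
    """Packaged table, default mixing variant (signed couplings)."""
    return b.load_contact_matrix()


@pytest.fixture(scope="session")
def uniform_matrix():
    """eps = -1 for every pair: residue identity drops out."""
    return b.ContactMatrix(np.full((20, 20), -1.0))


@pytest.fixture(scope="session")
def zero_matrix():
    """Athermal chain: excluded volume and bonds only."""
    return b.ContactMatrix(np.zeros((20, 20)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
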