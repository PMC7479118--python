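import numpy as np
import pytest

from mtweez import (
    Environment,
    FoldedDomainParams,
    HandleParams,
    PeptideParams,
)


@pytest.fixture
def env23():
    return Environment(23.0)


@pytest.fixture
def env37():
    return Environment(37.0)


@pytest.fixture
def i27_peptide():
    """Unfolded I27: 89 released residues at conventional peptide values."""
    return PeptideParams(n_residues=89)


@pytest.fixture
def i27_rod():
    return FoldedDomainParams(rod_length=4.4)


@pytest.fixture
def sr4_peptide():
    return PeptideParams(n_residues=104)


@pytest.fixture
def sr4_rod():
    return FoldedDomainParams(rod_length=5.0)


@pytest.fixture
def handle():
    return HandleParams(n_bp=572)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
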