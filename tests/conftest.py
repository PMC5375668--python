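import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from twilightseq.scoring import bundled_matrix, identity_model


@pytest.fixture(scope="session")
def blosum45():
    return bundled_matrix("BLOSUM45", 6)


@pytest.fixture(scope="session")
def pam250():
    return bundled_matrix("PAM250", 6)


@pytest.fixture(scope="session")
def amino_models(blosum45, pam250):
    return [blosum45, pam250]


@pytest.fixture(scope="session")
def nuc_identity():
    return identity_model(1)
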