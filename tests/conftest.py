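import numpy as np
import pytest

#: tetrahydropyranyl oxocarbenium -- smallest cyclic oxocarbenium cation
SMALL_CATION = "C1CC[O+]=CC1"
#: its 4-O-acetyl congener (ester-bearing, rotamer torsion resolvable)
ACYL_CATION = "CC(=O)OC1CC[O+]=CC1"


@pytest.fixture(scope="session")
def small_cation():
    return SMALL_CATION


@pytest.fixture(scope="session")
def acyl_cation():
    return ACYL_CATION


@pytest.fixture(scope="session")
def acyl_mol():
    from rdkit import Chem

    return Chem.AddHs(Chem.MolFromSmiles(ACYL_CATION))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
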