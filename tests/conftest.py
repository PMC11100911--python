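import numpy as np
import pytest

from keydiff.core import AtomCloud, LIGAND_VOCAB
from keydiff.synthetic import ToyComplexConfig, generate_toy_complex


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_complex(rng):
    return generate_toy_complex(ToyComplexConfig(), rng)


@pytest.fixture
def small_clouds(rng):
    """A random ligand/pocket pair sharing a frame (not a toy complex)."""
    lig = AtomCloud(
        rng.normal(0, 2, size=(6, 3)), LIGAND_VOCAB.one_hot(list("CCNOOF")), kind="ligand"
    )
    pocket = AtomCloud(
        rng.normal(0, 4, size=(15, 3)),
        LIGAND_VOCAB.one_hot(["C"] * 10 + ["N"] * 3 + ["O"] * 2),
        kind="pocket",
    )
    return pocket, lig


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
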