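import numpy as np
import pytest

from rwpot import RWParams, generate_fixture

SEQ30 = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"


@pytest.fixture(scope="session")
def params():
    return RWParams()


@pytest.fixture(scope="session")
def fixture30():
    """A 30-residue toy structure covering many residue types."""
    return generate_fixture(SEQ30, seed=7)


@pytest.fixture(scope="session")
def fixture50():
    return generate_fixture(SEQ30 + "MNPQRSTVWYACDEFGHIKL", seed=11)


def rigid_transform(structure, seed=0):
    """The same structure after a random rotation + translation."""
    from scipy.spatial.transform import Rotation
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-30, 30, 3)
    return structure.with_coords(structure.coords @ R.T + t)
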