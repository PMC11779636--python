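import numpy as np
import pytest

from saxsemble import Conformer, ConformerEnsemble, debye_profile, default_q_grid


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_conformer():
    """3 collinear beads 10 Å apart."""
    return Conformer("toy", [1, 2, 3], [[0.0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]])


@pytest.fixture
def random_cloud(rng):
    """25-bead random cloud at protein-ish scale."""
    coords = rng.normal(scale=15.0, size=(25, 3))
    return Conformer("cloud", np.arange(1, 26), coords)


@pytest.fixture
def small_ensemble(rng):
    """10 jittered copies of a random 12-bead structure."""
    base = rng.normal(scale=10.0, size=(12, 3))
    members = [
        Conformer(f"m{i}", np.arange(1, 13), base + rng.normal(scale=0.5, size=(12, 3)))
        for i in range(10)
    ]
    return ConformerEnsemble(members)


@pytest.fixture
def q_grid():
    return default_q_grid()


def random_rotation(rng):
    """A uniformly random proper rotation matrix (normalized random quaternion)."""
    from scipy.spatial.transform import Rotation

    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
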