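import numpy as np
import pytest

from pathmetad.geometry import Structure
from pathmetad.path_builder import extract_equispaced
from pathmetad.systems import make_mini_vft


@pytest.fixture(scope="session")
def mini_vft():
    """Default two-lobe model shared across tests (read-only)."""
    return make_mini_vft(seed=0)


@pytest.fixture(scope="session")
def hinge_frameset(mini_vft):
    """12-frame equispaced frame set along the rigid hinge path."""
    return extract_equispaced(mini_vft.rigid_hinge_path(101), 12, name="hinge")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_structure(rng, n_atoms=10, n_align=5, scale=1.0):
    """Random bead structure with the first n_align atoms tagged align."""
    coords = rng.normal(scale=scale, size=(n_atoms, 3))
    tags = ("align",) * n_align + ("measure",) * (n_atoms - n_align)
    return Structure(coords, subset_tags=tags)


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a random translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.normal(scale=2.0, size=3)
    return R, t
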