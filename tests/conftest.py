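import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from formindock import RigidTransform, Selection, make_subunit, resolve_selection
from formindock.synthetic import _structure_from_coords


def random_transform(rng) -> RigidTransform:
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.normal(0, 20, 3)
    return RigidTransform(R, t)


def chain_set(structure, chain_id, intervals=None, atom_names=("N", "CA", "C", "O")):
    return resolve_selection(structure, Selection(chain_id=chain_id,
                                                  intervals=intervals,
                                                  atom_names=atom_names))


def complete_chain(n_residues, seed=11, chain_id="A"):
    """Synthetic chain with residues 1..n, 4 backbone atoms each."""
    rng = np.random.default_rng(seed)
    coords = rng.normal(0, 15, (4 * n_residues, 3))
    return _structure_from_coords(coords, chain_id, sid=f"chain{n_residues}")


@pytest.fixture
def subunit():
    return make_subunit(200, seed=42)


@pytest.fixture
def small_subunit():
    return make_subunit(40, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
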