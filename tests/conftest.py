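import numpy as np
import pytest

import voxsite as vs


@pytest.fixture(scope="session")
def fixture_structure():
    """One synthetic pocket structure with its ground-truth site."""
    structure, sites = vs.generate_structure(vs.FixtureSpec(seed=11))
    return structure, sites


@pytest.fixture(scope="session")
def typed_structure(fixture_structure):
    structure, sites = fixture_structure
    return vs.strip_and_type_atoms(structure), sites


@pytest.fixture(scope="session")
def grid32():
    return vs.GridSpec(cube_size=32)


@pytest.fixture(scope="session")
def voxelized(typed_structure, grid32):
    typed, sites = typed_structure
    origins = vs.tile_origins(typed, grid32)
    assert len(origins) == 1
    return vs.voxelize(typed, origins[0], grid32), sites


def make_atom(coords, element="C", name="CA", resname="ALA",
              residue_id=("A", 1, ""), hetero=False):
    return vs.AtomRecord(element=element, coords=np.asarray(coords, float),
                         residue_name=resname, residue_id=residue_id,
                         name=name, is_hetero=hetero)


@pytest.fixture
def atom_factory():
    return make_atom
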