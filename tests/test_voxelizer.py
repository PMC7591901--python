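"""Density kernel, atom typing, tiling and voxelization."""

import numpy as np
import pytest

import voxsite as vs
from voxsite.voxelizer import _assign_channels


# ---------------------------------------------------------------------------
# density kernel

@pytest.mark.parametrize("r, cutoff, expected", [
    (0.0, 4.0, 1.0),
    (4.0, 4.0, np.exp(-8.0)),     # boundary included (<= cutoff)
    (4.0001, 4.0, 0.0),           # strictly beyond: exactly zero
    (1.0, 4.0, np.exp(-0.5)),
])
def test_density_values(r, cutoff, expected):
    assert vs.density(r, cutoff) == pytest.approx(expected, abs=1e-12)


def test_density_rejects_negative_distance():
    with pytest.raises(ValueError):
        vs.density(-0.1)


# ---------------------------------------------------------------------------
# stripping and channel typing

def test_strip_removes_water_ions_hydrogens(atom_factory):
    atoms = [
        atom_factory((0, 0, 0), element="C", name="CA"),
        atom_factory((1, 0, 0), element="H", name="HA"),
        atom_factory((2, 0, 0), element="O", name="O", resname="HOH",
                     residue_id=("A", 100, "")),
        atom_factory((3, 0, 0), element="NA", name="NA", resname="NA",
                     residue_id=("A", 101, "")),
    ]
    st = vs.strip_and_type_atoms(vs.ProteinStructure(atoms=atoms))
    assert len(st.atoms) == 1
    assert st.atoms[0].element == "C"


def test_empty_after_stripping_raises(atom_factory):
    water = atom_factory((0, 0, 0), element="O", name="O", resname="HOH")
    with pytest.raises(ValueError, match="empty structure"):
        vs.strip_and_type_atoms(vs.ProteinStructure(atoms=[water]))


def test_carbon_gets_element_and_hydrophobic_channels(atom_factory):
    ch = _assign_channels(atom_factory((0, 0, 0), element="C", name="CB"),
                          "default11")
    assert 0 in ch          # carbon element channel
    assert 4 in ch          # hydrophobic channel
    assert 10 in ch         # occupancy channel


def test_unknown_element_only_occupancy(atom_factory):
    ch = _assign_channels(atom_factory((0, 0, 0), element="SE", name="SE",
                                       resname="MSE"), "default11")
    assert ch == (10,)


def test_altloc_keeps_highest_occupancy(atom_factory):
    a = atom_factory((0, 0, 0))
    a.altloc, a.occupancy = "A", 0.4
    b = atom_factory((5, 0, 0))
    b.altloc, b.occupancy = "B", 0.6
    st = vs.strip_and_type_atoms(vs.ProteinStructure(atoms=[a, b]))
    assert len(st.atoms) == 1
    assert st.atoms[0].coords[0] == 5


# ---------------------------------------------------------------------------
# tiling

def _extent_structure(extents, atom_factory):
    atoms = [atom_factory((0, 0, 0)),
             atom_factory(extents, residue_id=("A", 2, ""))]
    return vs.strip_and_type_atoms(vs.ProteinStructure(atoms=atoms))


def _axis_tile_count_oracle(extent, spec):
    # smallest k with edge + stride*(k-1) >= extent
    k = 1
    while spec.cube_size * spec.voxel_size + spec.stride * spec.voxel_size * (k - 1) < extent:
        k += 1
    return k


@pytest.mark.parametrize("extents, expected_tiles", [
    ((60.0, 60.0, 60.0), 1),     # fits one cube
    ((100.0, 60.0, 60.0), 2),    # 64 + 48 = 112 >= 100
    ((160.0, 60.0, 60.0), 3),    # 64 + 2*48 = 160 exactly covers
])
def test_tile_counts_match_bruteforce(extents, expected_tiles, atom_factory):
    spec = vs.GridSpec()  # cube 64, stride 48
    st = _extent_structure(extents, atom_factory)
    origins = vs.tile_origins(st, spec)
    oracle = 1
    for e in extents:
        oracle *= _axis_tile_count_oracle(e, spec)
    assert len(origins) == oracle == expected_tiles


def test_every_atom_inside_some_tile(typed_structure, grid32):
    typed, _ = typed_structure
    origins = vs.tile_origins(typed, grid32)
    edge = grid32.edge_length
    for coords in typed.coords:
        assert any(np.all(coords >= o) and np.all(coords <= o + edge)
                   for o in origins)


# ---------------------------------------------------------------------------
# voxelization

def test_single_atom_at_voxel_center_gives_unit_density(atom_factory):
    spec = vs.GridSpec(cube_size=16)
    atom = atom_factory((4.5, 4.5, 4.5))
    st = vs.strip_and_type_atoms(vs.ProteinStructure(atoms=[atom]))
    grid = vs.voxelize(st, (0, 0, 0), spec)
    assert grid.values[4, 4, 4, 0] == pytest.approx(1.0, abs=1e-6)


def test_voxelize_matches_naive_double_loop(atom_factory):
    rng = np.random.default_rng(4)
    spec = vs.GridSpec(cube_size=16)
    atoms = [atom_factory(rng.uniform(2, 14, 3), residue_id=("A", i + 1, ""))
             for i in range(5)]
    st = vs.strip_and_type_atoms(vs.ProteinStructure(atoms=atoms))
    grid = vs.voxelize(st, (0, 0, 0), spec)
    # independent oracle: loop every voxel x every atom
    expected = np.zeros_like(grid.values)
    for i in range(16):
        for j in range(16):
            for k in range(16):
                center = np.array([i + 0.5, j + 0.5, k + 0.5])
                for a in st.atoms:
                    r = np.linalg.norm(center - a.coords)
                    rho = vs.density(r, spec.r_cutoff)
                    for c in a.channels:
                        expected[i, j, k, c] += rho
    assert np.allclose(grid.values, expected, atol=1e-5)


def test_density_additivity_for_disjoint_atom_sets(atom_factory):
    spec = vs.GridSpec(cube_size=16)
    a = [atom_factory((5, 5, 5))]
    b = [atom_factory((9, 9, 9), element="N", name="N",
                      residue_id=("A", 2, ""))]
    ga = vs.voxelize(vs.strip_and_type_atoms(vs.ProteinStructure(atoms=a)),
                     (0, 0, 0), spec)
    gb = vs.voxelize(vs.strip_and_type_atoms(vs.ProteinStructure(atoms=b)),
                     (0, 0, 0), spec)
    gab = vs.voxelize(vs.strip_and_type_atoms(vs.ProteinStructure(atoms=a + b)),
                      (0, 0, 0), spec)
    assert np.allclose(gab.values, ga.values + gb.values, atol=1e-6)


def test_two_identical_atoms_double_density(atom_factory):
    spec = vs.GridSpec(cube_size=16)
    one = vs.strip_and_type_atoms(vs.ProteinStructure(
        atoms=[atom_factory((6.5, 6.5, 6.5))]))
    grid1 = vs.voxelize(one, (0, 0, 0), spec)
    two = vs.ProteinStructure(atoms=[
        atom_factory((6.5, 6.5, 6.5)),
        atom_factory((6.5, 6.5, 6.5), name="CB", residue_id=("A", 2, ""))])
    grid2 = vs.voxelize(vs.strip_and_type_atoms(two), (0, 0, 0), spec)
    assert np.allclose(grid2.values, 2 * grid1.values, atol=1e-6)


def test_translation_equivariance(typed_structure, grid32):
    typed, _ = typed_structure
    origin = vs.tile_origins(typed, grid32)[0]
    shift = np.array([3.25, -7.5, 11.0])
    g0 = vs.voxelize(typed, origin, grid32)
    g1 = vs.voxelize(typed.translated(shift), origin + shift, grid32)
    assert np.array_equal(g0.values, g1.values)


def test_support_within_cutoff(voxelized, typed_structure, grid32):
    grid, _ = voxelized
    typed, _ = typed_structure
    nz = np.argwhere(grid.values.sum(axis=-1) > 0)
    centers = grid.origin + (nz + 0.5) * grid32.voxel_size
    # brute force: every nonzero voxel has an atom within r_cutoff
    for c in centers[:: max(1, len(centers) // 200)]:
        d = np.linalg.norm(typed.coords - c, axis=1)
        assert d.min() <= grid32.r_cutoff + 1e-9


def test_empty_grid_flag(grid32):
    zero = vs.VoxelGrid(origin=np.zeros(3),
                        values=np.zeros((32, 32, 32, 11), dtype=np.float32),
                        spec=grid32)
    assert vs.is_empty_grid(zero)
    one = vs.VoxelGrid(origin=np.zeros(3),
                       values=np.zeros((64, 64, 64, 11), dtype=np.float32),
                       spec=vs.GridSpec())
    one.values[0, 0, 0, 0] = 1.0
    # single unit voxel in 64^3 x 11: mean ~3.5e-7 < 1e-4
    assert vs.is_empty_grid(one)


def test_dense_tile_not_empty(voxelized):
    grid, _ = voxelized
    assert not vs.is_empty_grid(grid)


# ---------------------------------------------------------------------------
# config

def test_grid_spec_from_yaml(tmp_path):
    cfg = tmp_path / "grid.yaml"
    cfg.write_text("grid:\n  cube_size: 32\n  voxel_size: 0.5\n  r_cutoff: 3.0\n")
    spec = vs.load_grid_spec(cfg)
    assert spec.cube_size == 32
    assert spec.voxel_size == 0.5
    assert spec.r_cutoff == 3.0


def test_grid_spec_validation():
    with pytest.raises(ValueError):
        vs.GridSpec(cube_size=60)  # not divisible by 8
    with pytest.raises(ValueError):
        vs.GridSpec(r_cutoff=-1.0)
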