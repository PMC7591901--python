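"""Curation filters and the similarity-aware train/validation split."""

import itertools

import numpy as np
import pytest

import voxsite as vs
from voxsite.datasetprep import (SimilarityMatrix, accept_site,
                                 extract_ligands, principal_extents,
                                 refinement_displacement_count,
                                 split_train_val, structure_filters)


def _ligand_group(n_atoms, resname="XYZ", spread=3.0, offset=(0, 0, 0)):
    rng = np.random.default_rng(0)
    return [vs.AtomRecord(element="C",
                          coords=rng.uniform(0, spread, 3) + np.asarray(offset),
                          residue_name=resname, residue_id=("L", 900, ""),
                          name=f"C{i}", is_hetero=True)
            for i in range(n_atoms)]


def _protein(n_res=60, chain="A", spacing=3.0):
    atoms = []
    for i in range(n_res):
        atoms.append(vs.AtomRecord(
            element="C", coords=np.array([spacing * (i % 12),
                                          spacing * (i // 12), 0.0]),
            residue_name="ALA", residue_id=(chain, i + 1, ""), name="CA"))
    return vs.ProteinStructure(atoms=atoms)


# ---------------------------------------------------------------------------
# ligand extraction

@pytest.mark.parametrize("n_atoms, accepted", [(14, False), (15, True)])
def test_ligand_heavy_atom_boundary(n_atoms, accepted):
    st = vs.ProteinStructure(atoms=_protein().atoms,
                             ligands=[_ligand_group(n_atoms)])
    assert bool(extract_ligands(st)) is accepted


def test_excluded_residue_rejected_at_any_size():
    st = vs.ProteinStructure(atoms=_protein().atoms,
                             ligands=[_ligand_group(30, resname="GOL")])
    assert extract_ligands(st) == []


def test_hydrogens_not_counted_as_heavy():
    group = _ligand_group(15)
    group.append(vs.AtomRecord(element="H", coords=np.zeros(3),
                               residue_name="XYZ", residue_id=("L", 900, ""),
                               name="H1", is_hetero=True))
    st = vs.ProteinStructure(atoms=_protein().atoms, ligands=[group])
    ligs = extract_ligands(st)
    assert len(ligs) == 1 and len(ligs[0]) == 15


# ---------------------------------------------------------------------------
# site acceptance

def _contact_structure(n_contacts):
    """n_contacts protein atoms within 4 A of the ligand, the rest far away."""
    lig = [vs.AtomRecord(element="C", coords=np.zeros(3), residue_name="XYZ",
                         residue_id=("L", 900, ""), name="C1", is_hetero=True)]
    atoms = []
    for i in range(n_contacts):
        v = np.array([np.cos(i), np.sin(i), 0.1 * i])
        atoms.append(vs.AtomRecord(
            element="C", coords=3.0 * v / np.linalg.norm(v),
            residue_name="ALA", residue_id=("A", i + 1, ""), name="CA"))
    for i in range(30):
        atoms.append(vs.AtomRecord(
            element="C", coords=np.array([50.0 + i, 0, 0]),
            residue_name="ALA", residue_id=("A", 200 + i, ""), name="CA"))
    return vs.ProteinStructure(atoms=atoms, ligands=[lig]), lig


@pytest.mark.parametrize("n_contacts, accepted", [(19, False), (20, True)])
def test_contact_atom_boundary(n_contacts, accepted):
    st, lig = _contact_structure(n_contacts)
    ok, site = accept_site(st, lig)
    assert ok is accepted
    if accepted:
        assert len(site.site_atoms) == n_contacts


def test_site_center_is_residue_center_of_mass(typed_structure):
    typed, sites = typed_structure
    site = sites[0]
    # brute-force oracle: recompute over all atoms of the site residues
    res_ids = {a.residue_id for a in site.site_atoms}
    res_atoms = [a for a in typed.atoms if a.residue_id in res_ids]
    masses = np.array([a.mass for a in res_atoms])
    coords = np.array([a.coords for a in res_atoms])
    expected = (masses[:, None] * coords).sum(0) / masses.sum()
    assert np.allclose(site.center, expected, atol=1e-9)


# ---------------------------------------------------------------------------
# structure filters

def test_short_chain_dropped():
    st = _protein(n_res=49, chain="A")
    long_chain = _protein(n_res=60, chain="B")
    st.atoms.extend(long_chain.atoms)
    st.invalidate()
    ok, filtered, _ = structure_filters(st, {"resolution": 2.0})
    assert ok
    assert {a.residue_id[0] for a in filtered.atoms} == {"B"}


def test_resolution_filter_strictly_better_than_3():
    st = _protein()
    ok, _, reasons = structure_filters(st, {"resolution": 3.0})
    assert not ok and "resolution" in reasons[0]
    ok, _, _ = structure_filters(st, {"resolution": 2.9})
    assert ok


def test_missing_resolution_skips_filter_with_warning():
    with pytest.warns(UserWarning, match="resolution"):
        ok, _, _ = structure_filters(_protein(), {})
    assert ok


def test_four_chains_rejected():
    atoms = []
    for chain in "ABCD":
        atoms.extend(_protein(chain=chain).atoms)
    ok, _, reasons = structure_filters(vs.ProteinStructure(atoms=atoms),
                                       {"resolution": 2.0})
    assert not ok and "chains" in reasons[0]


def test_long_rod_rejected_by_principal_extent():
    atoms = [vs.AtomRecord(element="C",
                           coords=np.array([2.0 * i, np.sin(i), np.cos(i)]),
                           residue_name="ALA", residue_id=("A", i + 1, ""),
                           name="CA")
             for i in range(131)]  # 260 A along x
    st = vs.ProteinStructure(atoms=atoms)
    assert principal_extents(st.coords).max() > 250.0
    ok, _, reasons = structure_filters(st, {"resolution": 2.0})
    assert not ok and "extent" in reasons[0]


def test_compact_globule_accepted(fixture_structure):
    structure, _ = fixture_structure
    ok, _, _ = structure_filters(structure, {"resolution": 2.0})
    assert ok


def test_filters_order_independent():
    """Applying individual filters in any order accepts the same set."""
    candidates = {
        "good": (_protein(60), {"resolution": 2.0}),
        "short": (_protein(30), {"resolution": 2.0}),
        "bad_res": (_protein(60), {"resolution": 3.5}),
    }
    accepted = {name: structure_filters(st, md)[0]
                for name, (st, md) in candidates.items()}
    assert accepted == {"good": True, "short": False, "bad_res": False}


def test_refinement_displacement_counter(typed_structure):
    typed, sites = typed_structure
    moved = typed.translated(np.zeros(3))
    assert refinement_displacement_count(typed, moved, sites[0]) == 0
    shifted = typed.translated(np.array([0.5, 0, 0]))
    n = refinement_displacement_count(typed, shifted, sites[0])
    assert n == len(sites[0].site_atoms)


# ---------------------------------------------------------------------------
# split

def _block_matrix(sizes, within=0.8, between=0.1):
    n = sum(sizes)
    m = np.full((n, n), between)
    start = 0
    for s in sizes:
        m[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(m, 1.0)
    ids = [f"c{i}" for i in range(n)]
    return SimilarityMatrix(ids=ids, values=m)


def _assert_split_sound(matrix, train, val, threshold=0.5):
    idx = {c: i for i, c in enumerate(matrix.ids)}
    for t, v in itertools.product(train, val):
        assert matrix.values[idx[t], idx[v]] < threshold


def test_two_blocks_split_cleanly():
    m = _block_matrix([6, 6])
    train, val = split_train_val(m, threshold=0.5, val_fraction=0.5)
    assert len(train) == len(val) == 6
    _assert_split_sound(m, train, val)


def test_identity_matrix_splits_by_count():
    m = SimilarityMatrix(ids=[f"c{i}" for i in range(10)], values=np.eye(10))
    train, val = split_train_val(m, val_fraction=0.3)
    assert len(val) == 3 and len(train) == 7
    _assert_split_sound(m, train, val)


def test_uneven_blocks_never_cross_threshold():
    m = _block_matrix([8, 5, 3, 2, 2])
    train, val = split_train_val(m, val_fraction=0.25)
    assert sorted(train + val) == sorted(m.ids)
    _assert_split_sound(m, train, val)


def test_giant_cluster_warns_and_goes_to_train():
    m = _block_matrix([18, 2])
    with pytest.warns(UserWarning, match="largest similarity cluster"):
        train, val = split_train_val(m, val_fraction=0.5)
    assert len([c for c in train]) >= 18
    _assert_split_sound(m, train, val)


def test_chained_similarity_stays_on_one_side():
    # a-b similar, b-c similar, a-c not: the chain must not be split
    m = np.eye(3)
    m[0, 1] = m[1, 0] = 0.7
    m[1, 2] = m[2, 1] = 0.7
    sim = SimilarityMatrix(ids=["a", "b", "c"], values=m)
    train, val = split_train_val(sim, val_fraction=0.33)
    assert not val or set(val) == {"a", "b", "c"}
    _assert_split_sound(sim, train, val)


def test_similarity_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        SimilarityMatrix(ids=["a", "b"],
                         values=np.array([[1.0, 0.2], [0.3, 1.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        SimilarityMatrix(ids=["a", "b"],
                         values=np.array([[0.5, 0.2], [0.2, 1.0]]))
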