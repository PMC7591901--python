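"""Synthetic protein-like structures with planted, labeled binding sites.

Structures are compact heavy-atom clouds built on a jittered cubic lattice
at protein-interior density (~0.07 heavy atoms per cubic Angstrom),
organized into pseudo-residues with real residue/atom names so the channel
typer treats them like protein.  A concave pocket is carved as a spherical
cavity, a multi-atom ligand is placed inside it, and the ground-truth
binding site is computed with the same curation rules applied to real
structures — fixtures are therefore in-distribution for every pipeline
stage by construction.

The pseudo-residue alphabet covers hydrophobic, polar, charged and
aromatic chemistry but no rotamer geometry: atoms within a residue are not
bonded neighbors.  The pipeline only consumes elements, coordinates and
residue identity, so this is sufficient.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import gemmi
import numpy as np

from .datasetprep import CurationPolicy, accept_site
from .evaluation import BindingSite
from .voxelizer import AtomRecord, ProteinStructure

#: residue alphabet: (name, heavy-atom names); elements follow the first
#: letter of the atom name
RESIDUE_ALPHABET = (
    ("ALA", ("N", "CA", "C", "O", "CB")),
    ("SER", ("N", "CA", "C", "O", "CB", "OG")),
    ("VAL", ("N", "CA", "C", "O", "CB", "CG1", "CG2")),
    ("ASP", ("N", "CA", "C", "O", "CB", "CG", "OD1", "OD2")),
    ("LEU", ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2")),
    ("LYS", ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ")),
    ("PHE", ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ")),
    ("THR", ("N", "CA", "C", "O", "CB", "OG1", "CG2")),
)

LATTICE_SPACING = 2.4   # A; 1 / 2.4^3 ~ 0.072 atoms/A^3, protein-interior-like
LIGAND_SPACING = 1.35   # A between ligand heavy atoms


@dataclass
class FixtureSpec:
    """Study conditions of the synthetic corpus."""

    n_structures: int = 1
    atoms_per_structure: int = 440
    pocket_count: int = 1
    pocket_radius: float = 4.5
    ligand_heavy_atoms: int = 16
    noise_scale: float = 0.4
    box_extent: float = 24.0
    seed: int = 0

    def __post_init__(self):
        if self.ligand_heavy_atoms <= 14:
            raise ValueError("ligand_heavy_atoms must exceed 14 to pass curation")
        if self.pocket_radius + 2.0 >= self.box_extent / 2:
            raise ValueError("infeasible geometry: pocket larger than structure")


# ---------------------------------------------------------------------------
# Geometry helpers

def _ball_lattice(n_points: int, spacing: float, jitter: float,
                  rng: np.random.Generator) -> np.ndarray:
    """The n_points jittered lattice points nearest the origin."""
    r_max = spacing * int(np.ceil((n_points * 3 / (4 * np.pi)) ** (1 / 3))) + 2 * spacing
    k = int(np.ceil(r_max / spacing))
    ax = spacing * np.arange(-k, k + 1)
    pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = pts + rng.normal(0.0, jitter, size=pts.shape)
    order = np.argsort(np.linalg.norm(pts, axis=1), kind="stable")
    return pts[order[:n_points]]


def _fibonacci_sphere(n: int, rng: np.random.Generator) -> np.ndarray:
    """n roughly equidistant unit vectors (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    theta = np.pi * (1 + np.sqrt(5)) * i
    r = np.sqrt(1.0 - z ** 2)
    pts = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    # random orientation so the lining pattern is not shared across pockets
    q = rng.normal(size=(3, 3))
    u, _, vt = np.linalg.svd(q)
    rot = u @ vt
    if np.linalg.det(rot) < 0:
        rot[:, 0] *= -1
    return pts @ rot.T


def _pseudo_residues(coords: np.ndarray, chain: str = "A",
                     start: int = 1, hetero: bool = False,
                     resname: str | None = None) -> list[AtomRecord]:
    """Wrap a coordinate cloud into pseudo-residues with real PDB names."""
    atoms = []
    i = 0
    resnum = start
    alpha_idx = 0
    while i < len(coords):
        name, atom_names = RESIDUE_ALPHABET[alpha_idx % len(RESIDUE_ALPHABET)]
        alpha_idx += 1
        take = atom_names[:len(coords) - i]
        for an in take:
            atoms.append(AtomRecord(
                element=an[0], coords=coords[i], residue_name=resname or name,
                residue_id=(chain, resnum, ""), name=an, is_hetero=hetero))
            i += 1
        resnum += 1
    return atoms


def _make_ligand(center: np.ndarray, n_atoms: int,
                 rng: np.random.Generator) -> list[AtomRecord]:
    pts = _ball_lattice(n_atoms, LIGAND_SPACING, 0.12, rng) + center
    elements = (["C"] * 3 + ["N", "O"]) * (n_atoms // 5 + 1)
    return [AtomRecord(element=el, coords=p, residue_name="LIG",
                       residue_id=("L", 901, ""), name=f"{el}{j + 1}",
                       is_hetero=True)
            for j, (el, p) in enumerate(zip(elements, pts))]


# ---------------------------------------------------------------------------
# Structure generation

def generate_structure(spec: FixtureSpec, seed: int | None = None
                       ) -> tuple[ProteinStructure, list[BindingSite]]:
    """One compact pseudo-protein with ``pocket_count`` carved ligand pockets.

    Deterministic for a given seed.  Ground truth is computed by the
    curation rules (site = protein atoms within 4 A of the ligand; center =
    mass-weighted center of the site residues).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    pts = _ball_lattice(spec.atoms_per_structure, LATTICE_SPACING,
                        spec.noise_scale, rng)
    radius = np.linalg.norm(pts, axis=1).max()

    # pocket centers: random directions, buried below the surface
    depth = max(radius - spec.pocket_radius - 2.0, 0.0)
    centers = []
    for _ in range(spec.pocket_count):
        for _attempt in range(200):
            v = rng.normal(size=3)
            c = depth * v / np.linalg.norm(v)
            if all(np.linalg.norm(c - o) > 2 * spec.pocket_radius + 2.0
                   for o in centers):
                centers.append(c)
                break
        else:
            raise ValueError("infeasible geometry: cannot separate pockets")

    keep = np.ones(len(pts), dtype=bool)
    for c in centers:
        keep &= np.linalg.norm(pts - c, axis=1) > spec.pocket_radius
    protein_coords = pts[keep]

    ligands = [_make_ligand(c, spec.ligand_heavy_atoms, rng) for c in centers]
    for gi, grp in enumerate(ligands):
        for a in grp:
            a.residue_id = ("L", 901 + gi, "")

    # lining shells just outside each cavity: added outward until the site
    # clears the >= 20 contact-atom curation threshold with margin, giving
    # the cavity a protein-like concave wall
    policy = CurationPolicy()
    contact_target = policy.min_site_protein_atoms + 3
    lining: list[np.ndarray] = []
    for c, grp in zip(centers, ligands):
        lig_coords = np.array([a.coords for a in grp])

        def n_contacts() -> int:
            current = np.vstack([protein_coords] + ([np.array(lining)]
                                                    if lining else []))
            d = np.linalg.norm(current[:, None, :] - lig_coords[None], axis=2)
            return int(np.sum(d.min(axis=1) <= policy.site_distance))

        for dr in (0.5, 1.0, 1.5):
            if n_contacts() >= contact_target:
                break
            shell = _fibonacci_sphere(20, rng) * (spec.pocket_radius + dr) + c
            shell += rng.normal(0.0, 0.15, size=shell.shape)
            existing = np.vstack([protein_coords] + ([np.array(lining)]
                                                     if lining else []))
            for p in shell:
                if np.min(np.linalg.norm(existing - p, axis=1)) > 1.6:
                    lining.append(p)
        # last resort: drop single wall atoms right at contact range of a
        # ligand atom until the threshold clears
        for _attempt in range(200):
            if n_contacts() >= contact_target:
                break
            a = lig_coords[rng.integers(len(lig_coords))]
            v = rng.normal(size=3)
            p = a + (policy.site_distance - 0.7) * v / np.linalg.norm(v)
            existing = np.vstack([protein_coords] + ([np.array(lining)]
                                                     if lining else []))
            if (np.min(np.linalg.norm(existing - p, axis=1)) > 1.6
                    and np.min(np.linalg.norm(lig_coords - p, axis=1)) > 2.2):
                lining.append(p)
    if lining:
        protein_coords = np.vstack([protein_coords, np.array(lining)])

    structure = ProteinStructure(
        atoms=_pseudo_residues(protein_coords), ligands=ligands)

    sites = []
    for grp in ligands:
        ok, site = accept_site(structure, grp, policy)
        if not ok:
            raise ValueError(
                "generated pocket has too few lining atoms; increase "
                "atoms_per_structure or pocket burial")
        sites.append(site)
    return structure, sites


def generate_corpus(spec: FixtureSpec
                    ) -> list[tuple[ProteinStructure, list[BindingSite]]]:
    """``n_structures`` independent fixtures seeded from ``spec.seed``."""
    return [generate_structure(spec, seed=spec.seed + 1000 * i)
            for i in range(spec.n_structures)]


# ---------------------------------------------------------------------------
# Trajectories

def generate_trajectory(spec: FixtureSpec, n_frames: int, drift: float = 0.3,
                        pocket_window: tuple[int, int] | None = None,
                        seed: int | None = None):
    """A conformational ensemble around one fixture.

    Each frame perturbs the base structure with random per-atom
    displacements clipped to drift/2, bounding consecutive-frame RMSD by
    ``drift``.  With ``pocket_window`` = (f0, f1) the pocket exists only in
    frames f0 <= f < f1: outside the window the cavity is filled with
    protein atoms and the ligand is absent.  Returns (frames,
    sites_per_frame).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    base, sites = generate_structure(spec, seed=rng.integers(2 ** 31))

    plug_atoms: list[AtomRecord] = []
    if pocket_window is not None:
        # the atoms that would occupy the cavity in closed frames
        pts = _ball_lattice(spec.atoms_per_structure, LATTICE_SPACING,
                            spec.noise_scale,
                            np.random.default_rng((spec.seed or 0) + 7))
        site_center = sites[0].center
        lig_center = np.mean([a.coords for a in base.ligands[0]], axis=0)
        mask = np.linalg.norm(pts - lig_center, axis=1) <= spec.pocket_radius
        plug_atoms = _pseudo_residues(pts[mask], chain="B", start=1)

    frames = []
    sites_per_frame = []
    for f in range(n_frames):
        open_pocket = (pocket_window is None
                       or pocket_window[0] <= f < pocket_window[1])
        atoms = list(base.atoms) if open_pocket else list(base.atoms) + plug_atoms
        ligands = base.ligands if open_pocket else []
        if drift > 0:
            disp = rng.normal(0.0, drift / 4, size=(len(atoms), 3))
            norms = np.linalg.norm(disp, axis=1, keepdims=True)
            disp *= np.minimum(1.0, (drift / 2) / np.maximum(norms, 1e-12))
            atoms = [replace(a, coords=a.coords + d)
                     for a, d in zip(atoms, disp)]
        frames.append(ProteinStructure(atoms=atoms, ligands=ligands,
                                       model_index=f))
        sites_per_frame.append(sites if open_pocket else [])
    return frames, sites_per_frame


# ---------------------------------------------------------------------------
# PDB output

def _to_gemmi(structures: list[ProteinStructure]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "synthetic"
    for mi, s in enumerate(structures):
        model = gemmi.Model(mi + 1)
        chains: dict[str, gemmi.Chain] = {}
        residues: dict[tuple, gemmi.Residue] = {}
        for a in list(s.atoms) + [a for grp in s.ligands for a in grp]:
            if np.any(np.abs(a.coords) >= 10000):
                raise ValueError("coordinates outside PDB column range")
            chain_id = a.residue_id[0]
            if chain_id not in chains:
                chains[chain_id] = gemmi.Chain(chain_id)
            rkey = a.residue_id
            if rkey not in residues:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(int(a.residue_id[1]),
                                        a.residue_id[2] or " ")
                res.het_flag = "H" if a.is_hetero else "A"
                chains[chain_id].add_residue(res)
                residues[rkey] = len(chains[chain_id]) - 1
            res = chains[chain_id][residues[rkey]]
            atom = gemmi.Atom()
            atom.name = a.name or a.element
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.coords)
            atom.occ = a.occupancy
            res.add_atom(atom)
        for ch in chains.values():
            model.add_chain(ch)
        st.add_model(model)
    return st


def write_pdb(structure, path=None) -> str:
    """Write one structure (or a list of frames, as MODEL records) as PDB.

    Protein atoms become ATOM records, ligand atoms HETATM.  Coordinates
    round-trip through :func:`voxsite.voxelizer.read_pdb` at PDB precision
    (1e-3 A).
    """
    structures = structure if isinstance(structure, list) else [structure]
    text = _to_gemmi(structures).make_pdb_string()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
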