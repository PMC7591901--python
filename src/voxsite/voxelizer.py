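"""Protein structures as multi-channel 3D density images.

A protein is converted to a voxel grid in three steps: heavy atoms are
extracted from a PDB file and assigned to typed channels; the structure's
bounding box is covered with fixed-size cubic tiles; each tile is filled
with Gaussian atomic densities rho(r) = exp(-r^2/2) truncated at a cutoff
radius.  Tiles are the fixed-size inputs consumed by the detection network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import yaml

logger = logging.getLogger("voxsite")

# ---------------------------------------------------------------------------
# Constants

WATER_NAMES = {"HOH", "DOD", "WAT", "H2O"}

# Monatomic species commonly deposited as HETATM ions.
ION_NAMES = {
    "NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE", "CU", "NI", "CO", "CD",
    "HG", "SR", "CS", "BR", "IOD", "F", "LI", "RB", "BA", "AL", "NH4", "PB",
    "FE2", "CU1", "NI2", "ZN2", "MN3", "3CO", "YT3", "AU", "AG",
}

HYDROGEN_ELEMENTS = {"H", "D", "T"}

# Standard atomic masses for the heavy elements seen in protein structures.
ATOMIC_MASS = {
    "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974,
    "SE": 78.971, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "B": 10.81, "FE": 55.845, "ZN": 65.38, "MG": 24.305, "CA": 40.078,
    "NA": 22.990, "K": 39.098, "MN": 54.938, "CU": 63.546, "NI": 58.693,
}

AROMATIC_ATOMS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}

DONOR_ATOMS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"}, "ASN": {"ND2"}, "GLN": {"NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
}

ACCEPTOR_ATOMS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}

POSITIVE_ATOMS = {"ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}}
NEGATIVE_ATOMS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}

#: Channel order of the default 11-channel scheme: four element channels,
#: six physicochemical property channels, and one total-occupancy channel.
DEFAULT_CHANNELS = (
    "carbon", "nitrogen", "oxygen", "sulfur",
    "hydrophobic", "aromatic", "hbond_donor", "hbond_acceptor",
    "positive", "negative", "occupancy",
)

ELEMENT_CHANNEL = {"C": 0, "N": 1, "O": 2, "S": 3}


# ---------------------------------------------------------------------------
# Domain types

@dataclass
class AtomRecord:
    """One heavy atom: element, position (A), residue identity."""

    element: str
    coords: np.ndarray
    residue_name: str
    residue_id: tuple  # (chain id, residue number, insertion code)
    name: str = ""
    is_hetero: bool = False
    occupancy: float = 1.0
    altloc: str = ""
    channels: tuple[int, ...] | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")

    @property
    def mass(self) -> float:
        return ATOMIC_MASS.get(self.element.upper(), 12.011)


@dataclass
class ProteinStructure:
    """Heavy-atom protein model plus any bound ligand groups.

    ``atoms`` are the protein atoms; ``ligands`` is a list of HETATM groups
    kept separate from the protein (they define ground-truth binding sites
    and never enter the density image).  ``model_index`` identifies the
    ensemble frame for multi-model files.
    """

    atoms: list[AtomRecord]
    ligands: list[list[AtomRecord]] = field(default_factory=list)
    model_index: int = 0

    _coords: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def coords(self) -> np.ndarray:
        if self._coords is None or len(self._coords) != len(self.atoms):
            self._coords = (
                np.array([a.coords for a in self.atoms], dtype=float)
                if self.atoms else np.zeros((0, 3))
            )
        return self._coords

    def invalidate(self) -> None:
        self._coords = None

    @property
    def chains(self) -> dict[str, list[AtomRecord]]:
        out: dict[str, list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_id[0], []).append(a)
        return out

    def residues(self) -> dict[tuple, list[AtomRecord]]:
        """Protein residues keyed by (chain, resnum, icode), insertion order."""
        out: dict[tuple, list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_id, []).append(a)
        return out

    def translated(self, shift) -> "ProteinStructure":
        return self.transformed(np.eye(3), np.asarray(shift, dtype=float))

    def transformed(self, rot: np.ndarray, shift: np.ndarray,
                    center: np.ndarray | None = None) -> "ProteinStructure":
        """Rigid transform x -> R (x - c) + c + t applied to all atoms."""
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)

        def move(a: AtomRecord) -> AtomRecord:
            new = replace(a, coords=rot @ (a.coords - c) + c + shift)
            return new

        return ProteinStructure(
            atoms=[move(a) for a in self.atoms],
            ligands=[[move(a) for a in grp] for grp in self.ligands],
            model_index=self.model_index,
        )


@dataclass
class GridSpec:
    """Geometry of the voxel image and its tiling.

    cube_size voxels per tile edge, voxel_size A per voxel, tiles advance by
    ``stride`` voxels, densities truncated at ``r_cutoff`` A.
    """

    cube_size: int = 64
    voxel_size: float = 1.0
    stride: int | None = None  # defaults to 3/4 of cube_size (48 for 64)
    n_channels: int = 11
    r_cutoff: float = 4.0
    channel_scheme: str = "default11"

    def __post_init__(self):
        if self.stride is None:
            self.stride = self.cube_size * 3 // 4
        if self.cube_size % 8 != 0:
            raise ValueError("cube_size must be divisible by the cell edge (8 cells)")
        if self.stride > self.cube_size:
            raise ValueError("stride must not exceed cube_size")
        if self.r_cutoff <= 0:
            raise ValueError("r_cutoff must be positive")

    @property
    def cell_size(self) -> int:
        """Voxels per detection cell edge (the grid is always 8x8x8 cells)."""
        return self.cube_size // 8

    @property
    def edge_length(self) -> float:
        return self.cube_size * self.voxel_size


@dataclass
class VoxelGrid:
    """One tile: origin-anchored cube of per-channel atomic densities."""

    origin: np.ndarray
    values: np.ndarray  # (cube, cube, cube, n_channels)
    spec: GridSpec

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)


# ---------------------------------------------------------------------------
# PDB I/O

def _atom_from_gemmi(atom, residue, chain_name: str, het: bool) -> AtomRecord:
    return AtomRecord(
        element=atom.element.name.upper(),
        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
        residue_name=residue.name.strip(),
        residue_id=(chain_name, residue.seqid.num, residue.seqid.icode.strip()),
        name=atom.name.strip(),
        is_hetero=het,
        occupancy=atom.occ,
        altloc=atom.altloc if atom.altloc != "\x00" else "",
    )


def read_pdb(path) -> list[ProteinStructure]:
    """Read a PDB file into one ProteinStructure per MODEL.

    ATOM records become protein atoms; HETATM records are grouped per
    residue into ligand groups (waters and ions are read too and removed
    later by :func:`strip_and_type_atoms` / curation).
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    out = []
    for mi, model in enumerate(st):
        atoms: list[AtomRecord] = []
        hetero: dict[tuple, list[AtomRecord]] = {}
        for chain in model:
            for residue in chain:
                het = residue.het_flag == "H"
                for atom in residue:
                    rec = _atom_from_gemmi(atom, residue, chain.name, het)
                    if het:
                        key = (chain.name, residue.seqid.num,
                               residue.seqid.icode.strip(), residue.name)
                        hetero.setdefault(key, []).append(rec)
                    else:
                        atoms.append(rec)
        out.append(ProteinStructure(
            atoms=atoms, ligands=list(hetero.values()), model_index=mi))
    if not out:
        raise ValueError(f"no models found in {path}")
    return out


# ---------------------------------------------------------------------------
# Channel typing

def _assign_channels(atom: AtomRecord, scheme: str) -> tuple[int, ...]:
    if scheme != "default11":
        raise ValueError(f"unknown channel scheme: {scheme!r}")
    el = atom.element.upper()
    chans = [10]  # occupancy: every heavy atom
    if el in ELEMENT_CHANNEL:
        chans.append(ELEMENT_CHANNEL[el])
    else:
        logger.warning("unknown element %r: occupancy channel only", el)
        return tuple(sorted(chans))
    rn, an = atom.residue_name, atom.name
    if el == "C":
        chans.append(4)  # hydrophobic: carbon
    if an in AROMATIC_ATOMS.get(rn, ()):
        chans.append(5)
    if an == "N" or an in DONOR_ATOMS.get(rn, ()):
        chans.append(6)
    if an in ("O", "OXT") or an in ACCEPTOR_ATOMS.get(rn, ()):
        chans.append(7)
    if an in POSITIVE_ATOMS.get(rn, ()):
        chans.append(8)
    if an in NEGATIVE_ATOMS.get(rn, ()) or an == "OXT":
        chans.append(9)
    return tuple(sorted(chans))


def _is_ion_group(group: list[AtomRecord]) -> bool:
    return len(group) == 1 or group[0].residue_name.upper() in ION_NAMES


def strip_and_type_atoms(structure: ProteinStructure,
                         channel_scheme: str = "default11") -> ProteinStructure:
    """Remove hydrogens, waters and ions; keep one altloc; type each atom.

    Returns a new structure whose protein atoms carry channel assignments.
    Raises ``ValueError`` on an empty structure after stripping.
    """
    # resolve altlocs: highest occupancy wins, ties by altloc letter
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in structure.atoms:
        if a.element.upper() in HYDROGEN_ELEMENTS:
            continue
        if a.residue_name.upper() in WATER_NAMES or a.residue_name.upper() in ION_NAMES:
            continue
        key = (a.residue_id, a.name)
        cur = best.get(key)
        if cur is None:
            best[key] = a
            order.append(key)
        elif a.occupancy > cur.occupancy or (
                a.occupancy == cur.occupancy and a.altloc < cur.altloc):
            best[key] = a
    atoms = []
    for key in order:
        a = best[key]
        atoms.append(replace(a, channels=_assign_channels(a, channel_scheme)))
    if not atoms:
        raise ValueError("empty structure: no protein heavy atoms after stripping")
    ligands = [
        [replace(a, channels=_assign_channels(a, channel_scheme)) for a in grp
         if a.element.upper() not in HYDROGEN_ELEMENTS]
        for grp in structure.ligands
        if grp[0].residue_name.upper() not in WATER_NAMES and not _is_ion_group(grp)
    ]
    return ProteinStructure(atoms=atoms, ligands=[g for g in ligands if g],
                            model_index=structure.model_index)


# ---------------------------------------------------------------------------
# Density kernel and tiling

def density(r, r_cutoff: float = 4.0):
    """Truncated Gaussian atomic density exp(-r^2/2) for r <= r_cutoff, else 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    out = np.where(r <= r_cutoff, np.exp(-np.square(r) / 2.0), 0.0)
    return float(out) if out.ndim == 0 else out


def tile_origins(structure: ProteinStructure, spec: GridSpec) -> list[np.ndarray]:
    """Origins of the overlapping cubic tiles covering the structure.

    Tiles are anchored at the bounding-box minimum and advance by ``stride``
    voxels per axis until the box maximum lies inside the last tile, so every
    atom falls in at least one tile; a structure fitting in one cube yields
    exactly one origin.  Atoms outside a tile still contribute density within
    r_cutoff of its boundary, so no padding of the box is needed.
    """
    if not structure.atoms:
        raise ValueError("empty structure")
    coords = structure.coords
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    edge = spec.edge_length
    step = spec.stride * spec.voxel_size
    per_axis = []
    for ax in range(3):
        extent = hi[ax] - lo[ax]
        k = 1
        while edge + step * (k - 1) < extent:
            k += 1
        per_axis.append(lo[ax] + step * np.arange(k))
    gx, gy, gz = np.meshgrid(*per_axis, indexing="ij")
    return [np.array(o) for o in zip(gx.ravel(), gy.ravel(), gz.ravel())]


def voxelize(structure: ProteinStructure, origin, spec: GridSpec) -> VoxelGrid:
    """Fill one tile with per-channel atomic densities.

    Atoms outside the tile still contribute to voxels within r_cutoff of its
    boundary.  Voxel centers sit at origin + (i + 0.5) * voxel_size.
    """
    origin = np.asarray(origin, dtype=float)
    n, vs, rc = spec.cube_size, spec.voxel_size, spec.r_cutoff
    values = np.zeros((n, n, n, spec.n_channels), dtype=np.float32)
    axis_centers = origin[None, :] + (np.arange(n)[:, None] + 0.5) * vs

    half = rc / vs
    for a in structure.atoms:
        if a.channels is None:
            raise ValueError("atoms must be channel-typed before voxelization")
        # voxel index window possibly within r_cutoff of the atom
        rel = (a.coords - origin) / vs - 0.5
        lo = np.maximum(np.ceil(rel - half).astype(int), 0)
        hi = np.minimum(np.floor(rel + half).astype(int), n - 1)
        if np.any(lo > hi):
            continue
        dx = axis_centers[lo[0]:hi[0] + 1, 0] - a.coords[0]
        dy = axis_centers[lo[1]:hi[1] + 1, 1] - a.coords[1]
        dz = axis_centers[lo[2]:hi[2] + 1, 2] - a.coords[2]
        r2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
              + dz[None, None, :] ** 2)
        rho = np.where(r2 <= rc * rc, np.exp(-r2 / 2.0), 0.0).astype(np.float32)
        for c in a.channels:
            values[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1, c] += rho
    return VoxelGrid(origin=origin, values=values, spec=spec)


def voxelize_structure(structure: ProteinStructure,
                       spec: GridSpec) -> list[VoxelGrid]:
    """Tile the structure and voxelize every tile (convenience wrapper)."""
    return [voxelize(structure, o, spec) for o in tile_origins(structure, spec)]


def is_empty_grid(grid: VoxelGrid, threshold: float = 1e-4) -> bool:
    """True iff the mean density over all voxels and channels is < threshold."""
    return float(grid.values.mean()) < threshold


# ---------------------------------------------------------------------------
# Config

def load_grid_spec(path) -> GridSpec:
    """Load a GridSpec (and channel scheme) from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    fields = {k: v for k, v in cfg.get("grid", cfg).items()
              if k in GridSpec.__dataclass_fields__}
    return GridSpec(**fields)
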