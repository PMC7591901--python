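"""Training-corpus curation and the similarity-aware train/validation split.

Complexes enter the corpus only if the crystal is well resolved (< 3.0 A),
has fewer than four protein chains, keeps only chains of >= 50 residues,
and is globular (no principal-axis extent over 250 A).  Ligands are
non-detergent HETATM groups with more than 14 heavy atoms whose binding
site contains at least 20 protein heavy atoms within 4 A.  Chains are
split into train/validation so that no pair across the split has
structural similarity >= 0.5 (clusters of the similarity graph are
assigned whole to one side).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .evaluation import BindingSite
from .voxelizer import AtomRecord, ProteinStructure, ION_NAMES, WATER_NAMES

logger = logging.getLogger("voxsite")

#: Common crystallization additives (detergents, cryoprotectants, buffers)
#: that must not count as ligands.  User-extensible via CurationPolicy.
DEFAULT_EXCLUDED_RESIDUES = frozenset({
    # cryoprotectants / polyols
    "GOL", "EDO", "PEG", "PG4", "P6G", "1PE", "2PE", "PGE", "MPD", "MRD",
    # buffers
    "MES", "EPE", "TRS", "BTB", "CIT", "FLC", "CAC", "IMD", "BCT",
    # small anions / solvent
    "SO4", "PO4", "ACT", "ACY", "FMT", "NO3", "DMS", "BME", "MBN",
    # sugars used as cryoprotectants
    "GLC", "SUC", "TRE", "FRU", "MAN", "GAL", "NAG", "BMA", "XYS",
    # detergents
    "BOG", "LDA", "SDS", "DDM", "C8E", "LMT", "OLC", "PLM", "MYR",
})


@dataclass
class CurationPolicy:
    """Thresholds of the corpus curation filters."""

    max_resolution: float = 3.0        # exclusive: resolution must be better
    max_chains: int = 4                # exclusive: fewer than four chains
    min_chain_length: int = 50         # residues, inclusive
    min_ligand_heavy_atoms: int = 14   # exclusive: more than 14
    min_site_protein_atoms: int = 20   # inclusive: at least 20
    site_distance: float = 4.0         # A
    max_principal_extent: float = 250.0
    excluded_residue_names: frozenset = DEFAULT_EXCLUDED_RESIDUES

    def __post_init__(self):
        for name in ("max_resolution", "max_chains", "min_chain_length",
                     "min_ligand_heavy_atoms", "min_site_protein_atoms",
                     "site_distance", "max_principal_extent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise structural-similarity scores in [0, 1]."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match number of ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-8):
            raise ValueError("similarity matrix must have unit diagonal")


# ---------------------------------------------------------------------------
# Ligand and site extraction

def _heavy(group: Sequence[AtomRecord]) -> list[AtomRecord]:
    return [a for a in group if a.element.upper() not in ("H", "D", "T")]


def extract_ligands(structure: ProteinStructure,
                    policy: CurationPolicy = CurationPolicy()
                    ) -> list[list[AtomRecord]]:
    """HETATM groups with > 14 heavy atoms that are not solvent/additives."""
    out = []
    for group in structure.ligands:
        if not group:
            continue
        name = group[0].residue_name.upper()
        if name in WATER_NAMES or name in ION_NAMES:
            continue
        if name in policy.excluded_residue_names:
            continue
        heavy = _heavy(group)
        if len(heavy) > policy.min_ligand_heavy_atoms:
            out.append(heavy)
    return out


def accept_site(structure: ProteinStructure, ligand: Sequence[AtomRecord],
                policy: CurationPolicy = CurationPolicy()
                ) -> tuple[bool, BindingSite | None]:
    """Accept a ligand's site iff >= 20 protein heavy atoms lie within 4 A.

    The site center is the mass-weighted center of all heavy atoms of the
    residues contacting the ligand.
    """
    if not structure.atoms:
        return False, None
    tree = cKDTree(structure.coords)
    lig_coords = np.array([a.coords for a in ligand])
    contact_idx = sorted(set(
        i for idx in tree.query_ball_point(lig_coords, policy.site_distance)
        for i in idx))
    if len(contact_idx) < policy.min_site_protein_atoms:
        return False, None
    site_atoms = [structure.atoms[i] for i in contact_idx]
    site_residues = {a.residue_id for a in site_atoms}
    res_atoms = [a for a in structure.atoms if a.residue_id in site_residues]
    masses = np.array([a.mass for a in res_atoms])
    coords = np.array([a.coords for a in res_atoms])
    center = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    return True, BindingSite(ligand=list(ligand), site_atoms=site_atoms,
                             center=center)


# ---------------------------------------------------------------------------
# Structure-level filters

def principal_extents(coords: np.ndarray) -> np.ndarray:
    """Max-minus-min extent along each principal axis of the coordinates."""
    centered = coords - coords.mean(axis=0)
    cov = np.cov(centered.T)
    _, vecs = np.linalg.eigh(cov)
    proj = centered @ vecs
    return proj.max(axis=0) - proj.min(axis=0)


def structure_filters(structure: ProteinStructure, metadata: dict | None = None,
                      policy: CurationPolicy = CurationPolicy()
                      ) -> tuple[bool, ProteinStructure, list[str]]:
    """Apply resolution, chain-count, chain-length and extent filters.

    Short chains (< 50 residues) are dropped rather than failing the whole
    structure.  Returns (accepted, filtered structure, rejection reasons).
    A missing resolution entry skips that filter with a warning.
    """
    reasons: list[str] = []
    metadata = metadata or {}
    resolution = metadata.get("resolution")
    if resolution is None:
        warnings.warn("no resolution metadata: resolution filter skipped")
    elif resolution >= policy.max_resolution:
        reasons.append(f"resolution {resolution} not better than "
                       f"{policy.max_resolution}")

    chains: dict[str, set] = {}
    for a in structure.atoms:
        chains.setdefault(a.residue_id[0], set()).add(a.residue_id)
    if len(chains) >= policy.max_chains:
        reasons.append(f"{len(chains)} chains (need fewer than "
                       f"{policy.max_chains})")
    keep = {c for c, residues in chains.items()
            if len(residues) >= policy.min_chain_length}
    filtered = ProteinStructure(
        atoms=[a for a in structure.atoms if a.residue_id[0] in keep],
        ligands=structure.ligands, model_index=structure.model_index)
    if not filtered.atoms:
        reasons.append("no chain meets the minimum length")
    else:
        extents = principal_extents(filtered.coords)
        if extents.max() > policy.max_principal_extent:
            reasons.append(f"principal extent {extents.max():.0f} A exceeds "
                           f"{policy.max_principal_extent:.0f} A")
    return not reasons, filtered, reasons


def refinement_displacement_count(before: ProteinStructure,
                                  after: ProteinStructure,
                                  site: BindingSite,
                                  tol: float = 1e-3) -> int:
    """Number of binding-site atoms whose coordinates changed by > tol A
    between two versions of a structure (e.g. before/after refinement).

    Complexes where three or more site atoms moved should be discarded, as
    the refined conformation may no longer support the ligand pose.
    """
    after_coords = {(a.residue_id, a.name): a.coords for a in after.atoms}
    n = 0
    for a in site.site_atoms:
        other = after_coords.get((a.residue_id, a.name))
        if other is not None and np.linalg.norm(a.coords - other) > tol:
            n += 1
    return n


def curate_structure(structure: ProteinStructure, metadata: dict | None = None,
                     policy: CurationPolicy = CurationPolicy()
                     ) -> tuple[bool, ProteinStructure, list[BindingSite]]:
    """Full curation of one complex: filters + ligand/site extraction."""
    ok, filtered, _ = structure_filters(structure, metadata, policy)
    if not ok:
        return False, filtered, []
    sites = []
    for ligand in extract_ligands(filtered, policy):
        accepted, site = accept_site(filtered, ligand, policy)
        if accepted:
            sites.append(site)
    return bool(sites), filtered, sites


# ---------------------------------------------------------------------------
# Train/validation split

def split_train_val(matrix: SimilarityMatrix, threshold: float = 0.5,
                    val_fraction: float = 0.2
                    ) -> tuple[list[str], list[str]]:
    """Split chains so no train/val pair has similarity >= threshold.

    Chains are grouped into the connected components of the graph joining
    pairs with similarity >= threshold (the single-linkage clusters at that
    cut, which is exactly what guarantees the cross-cluster property).
    Components are then assigned whole to validation, largest first, while
    they fit the requested fraction.
    """
    n = len(matrix.ids)
    adj = csr_matrix(matrix.values >= threshold)
    n_comp, labels = connected_components(adj, directed=False)
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(i)
    target = int(round(val_fraction * n))
    giant = max(len(c) for c in clusters.values())
    if giant > n - target:
        warnings.warn("largest similarity cluster exceeds the training "
                      "budget; assigning it to train")
    val_idx: list[int] = []
    train_idx: list[int] = []
    # largest first, deterministic tie-break on first member
    for members in sorted(clusters.values(), key=lambda m: (-len(m), m[0])):
        if len(val_idx) + len(members) <= target:
            val_idx.extend(members)
        else:
            train_idx.extend(members)
    train = [matrix.ids[i] for i in sorted(train_idx)]
    val = [matrix.ids[i] for i in sorted(val_idx)]
    return train, val


def load_similarity_matrix(path) -> SimilarityMatrix:
    """Read a square labeled text table (TSV: header row + row labels)."""
    import pandas as pd
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return SimilarityMatrix(ids=[str(c) for c in df.columns],
                            values=df.to_numpy(dtype=float))
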