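"""Spatiotemporal binding-site analysis over conformational ensembles.

A conformational ensemble (molecular-dynamics frames, minimization steps,
multi-model PDB) is treated as a 3D video: the detector runs per frame,
and the resulting prediction cloud is grouped across frames with one of
three clustering algorithms (mean shift, DBSCAN, agglomerative — the
last optionally on binding-site residue sets under 1 - Jaccard distance).
Frames are assumed pre-aligned to a common reference frame.

Each cluster gets two scores over the F frames:

* score 1 — the per-frame maximum member score (0 where the cluster is
  absent) summed and divided by F;
* score 2 — the per-frame sum of member scores above a 0.1 step
  threshold, averaged over the frames where that sum is positive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import DBSCAN, AgglomerativeClustering, MeanShift

from .detector import DetectionModel, decode
from .postprocess import NmsParams, SitePrediction, assign_residues, nms
from .voxelizer import (GridSpec, ProteinStructure, is_empty_grid,
                        strip_and_type_atoms, tile_origins, voxelize)


# ---------------------------------------------------------------------------
# Per-frame prediction

@dataclass
class Predictor:
    """Single-structure pipeline: strip/type -> tile -> detect -> NMS."""

    model: DetectionModel
    spec: GridSpec
    nms_params: NmsParams = field(default_factory=NmsParams)
    residue_radius: float = 6.0

    def predict(self, structure: ProteinStructure,
                typed: bool = False) -> list[SitePrediction]:
        st = structure if typed else strip_and_type_atoms(structure)
        raw: list[SitePrediction] = []
        for origin in tile_origins(st, self.spec):
            grid = voxelize(st, origin, self.spec)
            if is_empty_grid(grid):
                continue
            tensor = self.model.predict_tile(grid)
            raw.extend(SitePrediction(center=rp.center, score=rp.score,
                                      frame=structure.model_index)
                       for rp in decode(tensor, self.spec))
        kept = nms(raw, self.nms_params)
        return [assign_residues(p, st, self.residue_radius) for p in kept]


@dataclass
class PredictionCloud:
    """All per-frame predictions of an ensemble, frame indices in [0, F)."""

    predictions: list[SitePrediction]
    n_frames: int


def predict_ensemble(frames: Sequence[ProteinStructure],
                     predictor) -> PredictionCloud:
    """Run the per-frame pipeline over an ensemble.

    ``predictor`` is any object with a ``predict(structure)`` method
    returning SitePredictions (normally :class:`Predictor`; tests may
    inject a stub).
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty ensemble")
    preds: list[SitePrediction] = []
    for f, st in enumerate(frames):
        st.model_index = f
        preds.extend(predictor.predict(st))
    return PredictionCloud(predictions=preds, n_frames=len(frames))


# ---------------------------------------------------------------------------
# Clustering

@dataclass
class SiteCluster:
    """A spatial group of predictions persisting across frames."""

    members: list[SitePrediction]
    center: np.ndarray
    score_max_avg: float
    score_meansum_avg: float
    #: per-frame maximum member score, length n_frames (0 where absent)
    frame_trace: np.ndarray
    is_noise: bool = False


def score_cluster(members: Sequence[SitePrediction], n_frames: int,
                  step_threshold: float = 0.1):
    """The two cluster scores plus the per-frame max-score trace."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    trace = np.zeros(n_frames)
    sums = np.zeros(n_frames)
    for p in members:
        trace[p.frame] = max(trace[p.frame], p.score)
        if p.score > step_threshold:
            sums[p.frame] += p.score
    score1 = float(trace.sum() / n_frames)
    present = sums > 0
    score2 = float(sums[present].mean()) if present.any() else 0.0
    return score1, score2, trace


def _jaccard_distance_matrix(residue_sets: list[frozenset]) -> np.ndarray:
    n = len(residue_sets)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = residue_sets[i], residue_sets[j]
            union = len(a | b)
            d[i, j] = d[j, i] = 1.0 - (len(a & b) / union if union else 0.0)
    return d


def cluster_cloud(cloud: PredictionCloud, method: str = "meanshift",
                  d_threshold: float = 8.0, eps: float | None = None,
                  min_samples: int = 5, bandwidth: float | None = None,
                  use_residues: bool = False,
                  jaccard_threshold: float = 0.5,
                  step_threshold: float = 0.1) -> list[SiteCluster]:
    """Group the prediction cloud into persistent site clusters.

    ``method`` is one of 'meanshift', 'dbscan', 'agglomerative'.  Clustering
    operates on Cartesian centers; the agglomerative method can instead use
    binding-site residue sets with 1 - Jaccard distance (``use_residues``).
    DBSCAN noise points become singleton clusters flagged ``is_noise``.
    """
    preds = cloud.predictions
    if not preds:
        raise ValueError("empty prediction cloud")
    X = np.array([p.center for p in preds])
    noise = np.zeros(len(preds), dtype=bool)
    if method == "meanshift":
        labels = MeanShift(bandwidth=bandwidth or d_threshold).fit_predict(X)
    elif method == "dbscan":
        labels = DBSCAN(eps=eps or d_threshold / 2,
                        min_samples=min_samples).fit_predict(X)
        noise = labels == -1
        next_label = labels.max() + 1 if (labels >= 0).any() else 0
        labels = labels.copy()
        for i in np.flatnonzero(noise):
            labels[i] = next_label
            next_label += 1
    elif method == "agglomerative":
        if len(preds) == 1:
            labels = np.zeros(1, dtype=int)
        elif use_residues:
            d = _jaccard_distance_matrix([p.residues for p in preds])
            labels = AgglomerativeClustering(
                n_clusters=None, distance_threshold=jaccard_threshold,
                metric="precomputed", linkage="average").fit_predict(d)
        else:
            labels = AgglomerativeClustering(
                n_clusters=None, distance_threshold=d_threshold,
                linkage="average").fit_predict(X)
    else:
        raise ValueError(f"unknown clustering method: {method!r}")

    clusters = []
    for lab in sorted(set(labels)):
        idx = np.flatnonzero(labels == lab)
        members = [preds[i] for i in idx]
        s1, s2, trace = score_cluster(members, cloud.n_frames, step_threshold)
        clusters.append(SiteCluster(
            members=members, center=X[idx].mean(axis=0),
            score_max_avg=s1, score_meansum_avg=s2, frame_trace=trace,
            is_noise=bool(noise[idx].all() and len(idx) == 1)))
    clusters.sort(key=lambda c: -c.score_max_avg)
    return clusters


# ---------------------------------------------------------------------------
# Windowed-mean RMSD (ligand/lipid mobility analysis)

def windowed_mean_rmsd(coords: np.ndarray, window: int = 100) -> np.ndarray:
    """Per-frame RMSD of an atom selection to its windowed mean conformation.

    ``coords`` has shape (F, N, 3).  For frame f the reference is the mean
    conformation over frames [f - window, f + window] (clipped to the
    trajectory); low values flag a selection that is locked in place.
    """
    coords = np.asarray(coords, dtype=float)
    f_tot = coords.shape[0]
    out = np.empty(f_tot)
    for f in range(f_tot):
        lo, hi = max(0, f - window), min(f_tot, f + window + 1)
        ref = coords[lo:hi].mean(axis=0)
        out[f] = np.sqrt(np.mean(np.sum((coords[f] - ref) ** 2, axis=1)))
    return out


# ---------------------------------------------------------------------------
# Output

def write_cluster_csv(clusters: Sequence[SiteCluster], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cluster", "x", "y", "z", "n_members",
                    "score_max_avg", "score_meansum_avg", "is_noise"])
        for i, c in enumerate(clusters):
            w.writerow([i, f"{c.center[0]:.3f}", f"{c.center[1]:.3f}",
                        f"{c.center[2]:.3f}", len(c.members),
                        f"{c.score_max_avg:.6f}", f"{c.score_meansum_avg:.6f}",
                        int(c.is_noise)])


def write_trace_csv(clusters: Sequence[SiteCluster], path) -> None:
    """Per-frame max-score trace per cluster, for replotting time curves."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "cluster", "max_score"])
        for i, c in enumerate(clusters):
            for f, s in enumerate(c.frame_trace):
                w.writerow([f, i, f"{s:.6f}"])
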