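"""Scoring protocol for binding-site detectors.

A prediction is matched to a true site under one of two correctness
criteria: the predicted center within d_threshold = 4 A of the true center
(center of mass of the binding-site residues), or the predicted center
within 4 A of the nearest ligand heavy atom.  Per true site only the
top-scored correct prediction counts as a true positive; every other
prediction is a false positive and unmatched sites are false negatives.

    Precision = N_TP / (N_TP + N_FP)        Recall = N_TP / (N_TP + N_FN)

Average precision is the area under the precision-recall curve obtained by
sweeping the score threshold over the pooled ranked predictions,
accumulated as an interpolation-free step sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .postprocess import SitePrediction
from .voxelizer import AtomRecord


# ---------------------------------------------------------------------------
# Types

@dataclass
class BindingSite:
    """Ground-truth site: the ligand, its contacting protein atoms, and the
    mass-weighted center of the binding-site residues."""

    ligand: list[AtomRecord]
    site_atoms: list[AtomRecord]
    center: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if not np.all(np.isfinite(self.center)):
            raise ValueError("site center must be finite")


@dataclass
class MatchCriterion:
    """How a prediction counts as correct: 'center' or 'ligand' mode, 4 A."""

    mode: str = "center"
    d_threshold: float = 4.0

    def __post_init__(self):
        if self.mode not in ("center", "ligand"):
            raise ValueError(f"unknown criterion mode: {self.mode!r}")
        if self.d_threshold <= 0:
            raise ValueError("d_threshold must be positive")


@dataclass
class EvalResult:
    n_tp: int
    n_fp: int
    n_fn: int
    precision: float
    recall: float
    ap: float
    #: pooled (score, is_tp) labels ranked by descending score
    labels: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Matching

def _distance_to_site(pred: SitePrediction, site: BindingSite,
                      crit: MatchCriterion) -> float:
    if crit.mode == "center":
        return float(np.linalg.norm(pred.center - site.center))
    lig = np.array([a.coords for a in site.ligand])
    return float(np.min(np.linalg.norm(lig - pred.center, axis=1)))


def _is_correct(d: float, crit: MatchCriterion) -> bool:
    # center mode: within the threshold (<=); ligand mode: strictly closer
    return d <= crit.d_threshold if crit.mode == "center" else d < crit.d_threshold


def match(preds: Sequence[SitePrediction], sites: Sequence[BindingSite],
          crit: MatchCriterion = MatchCriterion()):
    """Label predictions TP/FP against true sites, one-to-one.

    Predictions are scanned in descending score order; each is matched to
    the nearest still-unmatched site it is correct for, so per site the
    top-scored correct prediction is the TP.  Returns (labeled, unmatched)
    where labeled is [(prediction, is_tp), ...] sorted by descending score
    and unmatched is the list of FN sites.
    """
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].score, i))
    taken = [False] * len(sites)
    labeled = []
    for i in order:
        p = preds[i]
        best_j, best_d = -1, np.inf
        for j, site in enumerate(sites):
            if taken[j]:
                continue
            d = _distance_to_site(p, site, crit)
            if _is_correct(d, crit) and d < best_d:
                best_j, best_d = j, d
        if best_j >= 0:
            taken[best_j] = True
            labeled.append((p, True))
        else:
            labeled.append((p, False))
    unmatched = [s for s, t in zip(sites, taken) if not t]
    return labeled, unmatched


def precision_recall(n_tp: int, n_fp: int, n_fn: int) -> tuple[float, float]:
    """Exact precision/recall ratios; 0/0 is defined as 0."""
    p = n_tp / (n_tp + n_fp) if n_tp + n_fp > 0 else 0.0
    r = n_tp / (n_tp + n_fn) if n_tp + n_fn > 0 else 0.0
    return p, r


def average_precision(labels: Sequence[bool], n_sites: int) -> float:
    """Step-summed AP over a ranked label sequence.

    ``labels`` must be ordered by descending prediction score.  Each TP at
    rank k contributes (1 / n_sites) * precision@k; this equals the
    integral of p(r) over the recall steps.
    """
    if n_sites <= 0:
        raise ValueError("average precision requires at least one true site")
    ap = 0.0
    tp = 0
    for k, is_tp in enumerate(labels, start=1):
        if is_tp:
            tp += 1
            ap += (tp / k) / n_sites
    return ap


# ---------------------------------------------------------------------------
# Pooled evaluation

def evaluate(preds_per_structure: Sequence[Sequence[SitePrediction]],
             sites_per_structure: Sequence[Sequence[BindingSite]],
             crit: MatchCriterion = MatchCriterion(),
             top_n: bool = False) -> EvalResult:
    """Match per structure, pool the ranked labels, and compute AP.

    With ``top_n`` each structure's predictions are first truncated to its
    number of true sites (the Top-N protocol).
    """
    pooled: list[tuple[float, bool]] = []
    n_sites = n_fn = 0
    for preds, sites in zip(preds_per_structure, sites_per_structure):
        preds = list(preds)
        if top_n:
            preds = sorted(preds, key=lambda p: -p.score)[:len(sites)]
        labeled, unmatched = match(preds, sites, crit)
        pooled.extend((p.score, t) for p, t in labeled)
        n_sites += len(sites)
        n_fn += len(unmatched)
    pooled.sort(key=lambda st: -st[0])
    flags = [t for _, t in pooled]
    n_tp = sum(flags)
    n_fp = len(flags) - n_tp
    p, r = precision_recall(n_tp, n_fp, n_fn)
    ap = average_precision(flags, n_sites) if n_sites > 0 else 0.0
    return EvalResult(n_tp=n_tp, n_fp=n_fp, n_fn=n_fn,
                      precision=p, recall=r, ap=ap, labels=pooled)


def top_n_ap(preds_per_structure, sites_per_structure,
             crit: MatchCriterion = MatchCriterion()) -> float:
    """AP after truncating each structure to its N top-scored predictions."""
    return evaluate(preds_per_structure, sites_per_structure, crit,
                    top_n=True).ap


def family_breakdown(preds_per_structure, sites_per_structure,
                     families: Sequence[str],
                     crit: MatchCriterion = MatchCriterion(),
                     min_count: int = 20, top_n: bool = False) -> pd.DataFrame:
    """Per-family AP over families with at least ``min_count`` structures.

    ``families`` maps each structure (by position) to a family label
    supplied by the user; no database lookup is performed.
    """
    if not (len(preds_per_structure) == len(sites_per_structure)
            == len(families)):
        raise ValueError("one family label per structure required")
    rows = []
    for fam in sorted(set(families)):
        idx = [i for i, f in enumerate(families) if f == fam]
        if len(idx) < min_count:
            continue
        res = evaluate([preds_per_structure[i] for i in idx],
                       [sites_per_structure[i] for i in idx], crit, top_n=top_n)
        rows.append({"family": fam, "n_structures": len(idx), "ap": res.ap,
                     "n_tp": res.n_tp, "n_fp": res.n_fp, "n_fn": res.n_fn})
    return pd.DataFrame(rows, columns=["family", "n_structures", "ap",
                                       "n_tp", "n_fp", "n_fn"])
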