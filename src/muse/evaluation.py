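"""Metrics, the per-scale utilization-rate diagnostic, and contact scoring."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

#: Global decision-threshold grid swept by :func:`best_f1`.
THRESHOLD_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)


@dataclass
class MetricsReport:
    best_f1: float
    auroc: float
    auprc: float
    precision_at_k: Dict[int, float] = field(default_factory=dict)
    recall_at_k: Dict[int, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "best_f1": self.best_f1,
            "auroc": self.auroc,
            "auprc": self.auprc,
            "precision_at_k": dict(self.precision_at_k),
            "recall_at_k": dict(self.recall_at_k),
        }


@dataclass
class UtilizationReport:
    u_structure: float
    u_network: float
    f_multi: float
    f_no_structure: float
    f_no_network: float

    @property
    def ratio(self) -> float:
        return utilization_ratio(self.u_network, self.u_structure)


# ----------------------------------------------------------------------
# Threshold-swept micro F1
# ----------------------------------------------------------------------

def best_f1(scores: np.ndarray, labels: np.ndarray) -> float:
    """Micro-averaged F1 maximized over a global threshold grid.

    `scores` and `labels` are (n_links, n_classes) (a 1-D input is treated
    as a single class). Micro counting pools TP/FP/FN over all link-class
    cells; the same threshold applies to every class.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64).T).T
    labels = np.atleast_2d(np.asarray(labels, dtype=np.float64).T).T
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != labels.shape:
        raise ValueError(f"shape mismatch: {scores.shape} vs {labels.shape}")
    y = labels >= 0.5
    best = 0.0
    for thr in THRESHOLD_GRID:
        pred = scores >= thr
        tp = np.sum(pred & y)
        fp = np.sum(pred & ~y)
        fn = np.sum(~pred & y)
        denom = 2 * tp + fp + fn
        f1 = 2 * tp / denom if denom > 0 else 0.0
        if f1 > best:
            best = float(f1)
    return best


def f1_at_threshold(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> float:
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64) >= 0.5
    pred = scores >= threshold
    tp = np.sum(pred & y)
    fp = np.sum(pred & ~y)
    fn = np.sum(~pred & y)
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom > 0 else 0.0


# ----------------------------------------------------------------------
# Ranking metrics
# ----------------------------------------------------------------------

def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.float64).ravel()
    uniq = np.unique(labels >= 0.5)
    if uniq.size < 2:
        raise ValueError("both classes must be present")
    return (labels >= 0.5).astype(np.int64)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUROC with midrank tie handling."""
    y = _check_binary(labels)
    return float(roc_auc_score(y, np.asarray(scores, dtype=np.float64).ravel()))


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (step-wise interpolation)."""
    y = _check_binary(labels)
    return float(
        average_precision_score(y, np.asarray(scores, dtype=np.float64).ravel())
    )


def precision_recall_at_k(
    scores: np.ndarray, labels: np.ndarray, k: int
) -> tuple:
    """Precision and recall over the k top-scored pairs."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = (np.asarray(labels, dtype=np.float64).ravel() >= 0.5)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > scores.size:
        raise ValueError(f"k={k} exceeds number of pairs {scores.size}")
    order = np.argsort(-scores, kind="stable")[:k]
    hits = int(labels[order].sum())
    total_pos = int(labels.sum())
    precision = hits / k
    recall = hits / total_pos if total_pos > 0 else 0.0
    return float(precision), float(recall)


def label_interchain_contacts(
    coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float = 6.0
) -> np.ndarray:
    """Binary inter-chain contact matrix: (i,j)=1 iff distance < cutoff Å."""
    coords_a = np.asarray(coords_a, dtype=np.float64)
    coords_b = np.asarray(coords_b, dtype=np.float64)
    if coords_a.size == 0 or coords_b.size == 0:
        raise ValueError("chains must be nonempty")
    from scipy.spatial.distance import cdist

    return (cdist(coords_a, coords_b) < cutoff).astype(np.int64)


# ----------------------------------------------------------------------
# Utilization-rate diagnostic
# ----------------------------------------------------------------------

def utilization_rate(f_multi: float, f_single: float) -> float:
    """Relative accuracy change from adding a scale: (f(M) − f(M')) / f(M')."""
    if f_single == 0:
        raise ValueError("single-scale accuracy must be positive")
    return (f_multi - f_single) / f_single


def utilization_ratio(u_network: float, u_structure: float) -> float:
    """u_network / u_structure, truncated (not rounded) to two decimals."""
    if u_structure == 0:
        raise ValueError("structure-scale utilization rate must be nonzero")
    ratio = u_network / u_structure
    return math.trunc(ratio * 100.0) / 100.0


def metrics_report(
    scores: np.ndarray,
    labels: np.ndarray,
    ks: Optional[tuple] = None,
) -> MetricsReport:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    flat_scores = scores.ravel()
    flat_labels = labels.ravel()
    report = MetricsReport(
        best_f1=best_f1(scores, labels),
        auroc=auroc(flat_scores, flat_labels),
        auprc=auprc(flat_scores, flat_labels),
    )
    if ks:
        for k in ks:
            p, r = precision_recall_at_k(flat_scores, flat_labels, k)
            report.precision_at_k[k] = p
            report.recall_at_k[k] = r
    return report
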