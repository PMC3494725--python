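"""Ranking evaluation: precision/recall curves, ROC and AUC.

All evaluators operate on a ranked list of pairs (descending combined
score).  AUC is the probability that a random positive outscores a random
negative, with ties counted half — equivalently the trapezoidal area under
the ROC polyline.  For repeated cross-validation runs the per-repetition
ROC curves are averaged pointwise on a fixed false-positive-rate grid; both
the mean of the per-curve AUCs and the AUC of the mean curve are reported,
since the two differ in general.

Ties in precision/recall ranking are broken by the canonical pair identity
so that curves are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .datamodel import ValidationError

__all__ = [
    "EvaluationCurves",
    "precision_recall_at_k",
    "roc_auc",
    "mean_curves",
    "ROC_GRID_POINTS",
]

ROC_GRID_POINTS = 1001


def _check_two_classes(labels: np.ndarray) -> None:
    u = set(np.unique(labels).tolist())
    if u != {0, 1}:
        raise ValidationError(
            f"need both a positive and a negative class, got labels {sorted(u)}"
        )


@dataclass
class EvaluationCurves:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValidationError(f"AUC out of [0,1]: {self.auc}")


def precision_recall_at_k(
    scores: np.ndarray,
    labels: np.ndarray,
    pair_ids: list | None = None,
) -> dict[str, np.ndarray]:
    """Precision@k and recall@k for every cut-off k = 1..n.

    precision@k = TP(k)/k, recall@k = TP(k)/#pos after sorting by
    descending score (ties resolved by canonical pair id, then input
    order).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    _check_two_classes(y)
    if pair_ids is not None:
        order = sorted(range(len(s)), key=lambda i: (-s[i], pair_ids[i]))
        order = np.asarray(order)
    else:
        order = np.lexsort((np.arange(len(s)), -s))
    ranked = y[order]
    tp = np.cumsum(ranked == 1)
    k = np.arange(1, len(s) + 1)
    return {
        "order": order,
        "precision": tp / k,
        "recall": tp / (y == 1).sum(),
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> EvaluationCurves:
    """ROC polyline and its area.

    Tied scores form a single ROC step (diagonal segment), so the
    trapezoidal area equals the Mann-Whitney probability with half credit
    for ties.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    _check_two_classes(y)
    if not np.all(np.isfinite(s)):
        raise ValidationError("non-finite score")
    fpr, tpr, _ = _roc_curve(y, s, drop_intermediate=False)
    return EvaluationCurves(fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


def mean_curves(
    curves: list[EvaluationCurves], n_grid: int = ROC_GRID_POINTS
) -> dict:
    """Pointwise mean and sd of ROC curves resampled on a common FPR grid.

    Returns the grid, mean/sd TPR, the mean of the per-curve AUCs (with its
    sd) and, separately, the AUC of the mean curve.
    """
    if len(curves) < 2:
        raise ValidationError("need >= 2 curves to average")
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = np.stack([np.interp(grid, c.fpr, c.tpr) for c in curves])
    aucs = np.array([c.auc for c in curves])
    mean_tpr = tprs.mean(axis=0)
    return {
        "fpr_grid": grid,
        "mean_tpr": mean_tpr,
        "sd_tpr": tprs.std(axis=0, ddof=1),
        "mean_auc": float(aucs.mean()),
        "sd_auc": float(aucs.std(ddof=1)),
        "auc_of_mean_curve": float(_trapezoid_auc(grid, mean_tpr)),
    }
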