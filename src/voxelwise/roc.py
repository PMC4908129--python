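"""Voxel-wise ROC analysis.

At each voxel the image intensity is treated as a decision variable for a
binary classification (e.g. does this subject progress to dementia), with
the rule "predict positive when value >= threshold" by default (higher
uptake = more at-risk; flip with ``direction="lower"``). The empirical ROC
curve over all distinct thresholds yields TPR = TP / condition-positive and
FPR = FP / condition-negative; AUC is the trapezoid area, which equals the
tie-corrected Mann-Whitney rank statistic. The reported operating point is
the Youden-optimal threshold (maximizing TPR - FPR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parcellation import ParcelMap, parcellate, scatter_gather
from .volio import VoxelMatrix

__all__ = ["ROCMaps", "voxelwise_roc", "roc_curve_single"]


@dataclass
class ROCMaps:
    """Per-voxel ROC summaries (all arrays length tau)."""

    auc: np.ndarray
    tpr_at_opt: np.ndarray
    fpr_at_opt: np.ndarray
    threshold_opt: np.ndarray
    positive_label: object
    direction: str = "higher"


def roc_curve_single(
    values: np.ndarray, positive: np.ndarray, direction: str = "higher"
):
    """Empirical ROC for one voxel: ``(thresholds, tpr, fpr, auc)``.

    Thresholds are the distinct data values (ties collapse to a single
    threshold); the curve starts at (0,0) (threshold above every value) and
    ends at (1,1).
    """
    values = np.asarray(values, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    sign = -1.0 if direction == "lower" else 1.0
    v = sign * values
    order = np.argsort(-v, kind="stable")  # descending: most-positive-predicted first
    v_sorted = v[order]
    pos_sorted = positive[order]
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    # collapse ties: last index of each run of equal values
    is_last = np.append(v_sorted[:-1] != v_sorted[1:], True)
    tp = np.cumsum(pos_sorted)[is_last]
    fp = np.cumsum(~pos_sorted)[is_last]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    thresholds = sign * v_sorted[is_last]
    auc = float(np.trapezoid(tpr, fpr))
    return thresholds, tpr, fpr, auc


def voxelwise_roc(
    matrix: VoxelMatrix,
    labels,
    positive_label=None,
    pm: ParcelMap | None = None,
    direction: str = "higher",
    n_jobs: int = 1,
) -> ROCMaps:
    """Per-voxel AUC, Youden-optimal TPR/FPR and operating-threshold maps.

    ``labels`` is a length-n vector; ``positive_label`` names the
    condition-positive class (default: the larger label value). Both
    classes must be present.
    """
    labels = np.asarray(labels)
    if labels.size != matrix.n_subjects:
        raise ValueError(
            f"{labels.size} labels for {matrix.n_subjects} subjects"
        )
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"classification variable must have exactly 2 classes, got {uniq!r}")
    if positive_label is None:
        positive_label = uniq[-1]
    elif positive_label not in uniq:
        raise ValueError(f"positive label {positive_label!r} not among classes {uniq!r}")
    positive = labels == positive_label
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    if pm is None:
        pm = parcellate(matrix.tau, min(200, matrix.tau))

    def worker(cols: np.ndarray, idx: np.ndarray) -> np.ndarray:
        out = np.empty((4, cols.shape[1]))
        for c in range(cols.shape[1]):
            thr, tpr, fpr, auc = roc_curve_single(cols[:, c], positive, direction)
            youden = tpr - fpr
            k = int(np.argmax(youden[1:])) + 1  # skip the (0,0) point
            out[:, c] = (auc, tpr[k], fpr[k], thr[k - 1])
        return out

    res = scatter_gather(matrix, pm, worker, n_jobs=n_jobs)
    return ROCMaps(
        auc=res[0],
        tpr_at_opt=res[1],
        fpr_at_opt=res[2],
        threshold_opt=res[3],
        positive_label=positive_label,
        direction=direction,
    )
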