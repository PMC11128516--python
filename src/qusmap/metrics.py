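"""Classification and detection metrics against ground-truth masks.

Pixelwise confusion metrics (ACC/SEN/SPE), rank-based ROC-AUC, and the
detection-quality triple: area detection accuracy
ADA = (1 - |A_truth - A_detected| / A_truth) * 100 %, Dice score
DS = 2TP / (2TP + FP + FN), and the Hausdorff distance between foreground
pixel sets (standard max-min directed form; the symmetric variant is used
for reports).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.metrics import roc_auc_score

from .config import ParameterError
from .detect import BinaryMask


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @classmethod
    def from_masks(cls, pred: np.ndarray, truth: np.ndarray) -> "ConfusionCounts":
        p = np.asarray(pred).astype(bool)
        t = np.asarray(truth).astype(bool)
        if p.shape != t.shape:
            raise ParameterError("prediction and truth shapes differ")
        return cls(
            TP=int(np.sum(p & t)),
            FP=int(np.sum(p & ~t)),
            TN=int(np.sum(~p & ~t)),
            FN=int(np.sum(~p & t)),
        )


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(ACC, SEN, SPE); a zero denominator yields NaN rather than an error."""
    total = counts.total
    acc = (counts.TP + counts.TN) / total if total else math.nan
    pos = counts.TP + counts.FN
    sen = counts.TP / pos if pos else math.nan
    neg = counts.TN + counts.FP
    spe = counts.TN / neg if neg else math.nan
    return acc, sen, spe


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-statistic AUC of continuous scores against a binary truth mask."""
    t = np.asarray(truth).astype(bool).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if t.shape != s.shape:
        raise ParameterError("scores and truth shapes differ")
    if t.all() or not t.any():
        raise ParameterError("truth mask must contain both classes")
    return float(roc_auc_score(t.astype(int), s))


def area_detection_accuracy(truth_area: float, detected_area: float) -> float:
    """ADA in percent; can be negative for gross over-detection."""
    truth_area = float(truth_area)
    detected_area = float(detected_area)
    if truth_area <= 0:
        raise ParameterError("truth area must be positive")
    return (1.0 - abs(truth_area - detected_area) / truth_area) * 100.0


def dice_score(counts: ConfusionCounts) -> float:
    denom = 2 * counts.TP + counts.FP + counts.FN
    if denom == 0:
        return math.nan  # both masks empty: undefined
    return 2 * counts.TP / denom


def _foreground_points(mask, boundary_only: bool) -> np.ndarray:
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask)
    data = data.astype(bool)
    if boundary_only:
        from scipy import ndimage

        eroded = ndimage.binary_erosion(data)
        data = data & ~eroded
    pts = np.argwhere(data)
    if len(pts) == 0:
        raise ParameterError("empty mask has no Hausdorff distance")
    return pts.astype(float)


def hausdorff_distance(
    pred,
    truth,
    symmetric: bool = True,
    boundary_only: bool = False,
    max_max: bool = False,
) -> float:
    """Hausdorff distance between foreground pixel sets, in pixels.

    Default is the standard max-min form (symmetric: max over both
    directions).  ``max_max`` computes the max-max form instead (a set
    diameter, kept for auditability only).
    """
    a = _foreground_points(pred, boundary_only)
    b = _foreground_points(truth, boundary_only)
    if max_max:
        from scipy.spatial.distance import cdist

        return float(cdist(a, b).max())
    d_ab = cKDTree(b).query(a)[0].max()
    if not symmetric:
        return float(d_ab)
    d_ba = cKDTree(a).query(b)[0].max()
    return float(max(d_ab, d_ba))
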