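"""Pixelwise segmentation metrics and ROC threshold sweeps.

Every pixel of a segmentation is one binary classification with vein as the
positive class; the standard rates follow from the confusion counts:

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (P + N)

ROC curves are produced by overriding the entropy-selected threshold with
every candidate gray level and re-scoring, optionally with the morphological
postprocessing applied at each operating point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import entropy_threshold, morphology
from .errors import ValidationError

__all__ = ["ConfusionCounts", "EvalScores", "ROCPoint", "confusion", "scores",
           "roc_sweep", "roc_auc"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class EvalScores:
    sensitivity: float
    specificity: float
    accuracy: float


@dataclass(frozen=True)
class ROCPoint:
    threshold: int
    fpr: float
    tpr: float
    accuracy: float


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Confusion counts of a predicted mask against ground truth (vein = positive)."""
    p, t = np.asarray(pred), np.asarray(truth)
    if p.shape != t.shape:
        raise ValidationError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    p, t = p.astype(bool), t.astype(bool)
    return ConfusionCounts(
        tp=int((p & t).sum()),
        tn=int((~p & ~t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def scores(counts: ConfusionCounts) -> EvalScores:
    """Sensitivity, specificity and accuracy from confusion counts."""
    if counts.p == 0 or counts.n == 0:
        raise ValidationError(
            f"metrics undefined: P={counts.p}, N={counts.n} (need both classes in truth)"
        )
    return EvalScores(
        sensitivity=counts.tp / counts.p,
        specificity=counts.tn / counts.n,
        accuracy=(counts.tp + counts.tn) / (counts.p + counts.n),
    )


def roc_sweep(enh: np.ndarray, truth: np.ndarray, levels: int = 256,
              postprocess: bool = True, dilate_len: int = 5,
              majority_max_iter: int = 100) -> list[ROCPoint]:
    """Operating points from sweeping the binarization threshold.

    Thresholds run from -1 (everything vein) through every t in [0, L-2] to
    L-1 (everything background), in that order, so both ROC endpoints are
    included.  With ``postprocess`` the configured dilation and majority
    filtering are applied at every threshold, matching the full pipeline.
    """
    q = entropy_threshold.quantize(enh, levels)
    t_arr = np.asarray(truth).astype(bool)
    points = []
    for t in range(-1, levels):
        mask = (q > t).astype(np.uint8)
        if postprocess and 0 <= t <= levels - 2:
            mask = morphology.dilate_line_x(mask, dilate_len)
            mask = morphology.majority_fixpoint(mask, majority_max_iter)
        c = confusion(mask, t_arr)
        s = scores(c)
        points.append(ROCPoint(threshold=t, fpr=1.0 - s.specificity,
                               tpr=s.sensitivity, accuracy=s.accuracy))
    return points


def roc_auc(points: list[ROCPoint]) -> float:
    """Area under the ROC polyline (trapezoidal, sorted by false-positive rate)."""
    fpr = np.array([p.fpr for p in points])
    tpr = np.array([p.tpr for p in points])
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))
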