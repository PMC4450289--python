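"""Co-occurrence local-entropy thresholding.

The enhanced residual image is segmented into concave (vein) and non-concave
regions with a threshold chosen from the gray-level co-occurrence matrix of
adjacent pixels rather than from the histogram: two images with identical
histograms but different spatial arrangement give different co-occurrence
matrices, hence different entropy curves and thresholds.

For a candidate threshold ``t`` the co-occurrence matrix splits into four
quadrants; the within-class transitions are the background-background block
(levels <= t on both axes) and the foreground-foreground block (levels > t).
Each block is normalized by its own mass and its Shannon entropy (base 2,
with 0*log 0 := 0) is computed; the selected threshold maximizes
``H(t) = H_BB(t) + H_FF(t)``.  The off-diagonal (edge transition) quadrants
are excluded and normalization is per quadrant; these two choices are this
package's reconstruction of the second-order local-entropy criterion and are
isolated here so an alternative split can be swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "CoocMatrix",
    "ThresholdResult",
    "quantize",
    "cooccurrence",
    "quadrant_entropies",
    "select_threshold",
    "binarize",
]


@dataclass(frozen=True)
class CoocMatrix:
    """L x L adjacent-pixel gray-level transition counts (right + below)."""

    counts: np.ndarray

    @property
    def levels(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ThresholdResult:
    """Selected gray-level threshold and the full entropy curve H(t)."""

    t_star: int
    entropy_curve: np.ndarray


def quantize(enh: np.ndarray, levels: int = 256) -> np.ndarray:
    """Map a [0, 1] field to integer gray levels 0 .. levels-1 (round-half-up)."""
    arr = np.asarray(enh, dtype=np.float64)
    if levels < 2:
        raise ValidationError(f"need at least 2 gray levels, got {levels}")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValidationError(
            f"values outside [0, 1]: min={arr.min():.4g}, max={arr.max():.4g}"
        )
    return np.floor(arr * (levels - 1) + 0.5).astype(np.int64)


def cooccurrence(qimg: np.ndarray, levels: int | None = None) -> CoocMatrix:
    """Asymmetric co-occurrence counts over right and below neighbor pairs.

    The total count always equals ``rows*(cols-1) + (rows-1)*cols``.
    """
    q = np.asarray(qimg)
    if q.ndim != 2 or (q.shape[0] < 2 and q.shape[1] < 2):
        raise ValidationError(f"need at least one adjacent pixel pair, got shape {q.shape}")
    if levels is None:
        levels = int(q.max()) + 1
    pairs_r = q[:, :-1].ravel() * levels + q[:, 1:].ravel()
    pairs_d = q[:-1, :].ravel() * levels + q[1:, :].ravel()
    flat = np.bincount(np.concatenate([pairs_r, pairs_d]), minlength=levels * levels)
    return CoocMatrix(counts=flat.reshape(levels, levels))


def _quadrant_entropy(block: np.ndarray) -> float:
    s = block.sum()
    if s == 0:
        return 0.0
    p = block[block > 0] / s
    return float(-(p * np.log2(p)).sum())


def quadrant_entropies(cooc: CoocMatrix, t: int) -> tuple[float, float]:
    """Within-quadrant entropies (H_BB, H_FF) at threshold ``t``.

    Each quadrant is normalized by its own mass; an empty quadrant
    contributes zero entropy.
    """
    levels = cooc.levels
    if not 0 <= t <= levels - 2:
        raise ValidationError(f"threshold {t} outside [0, {levels - 2}]")
    c = cooc.counts.astype(np.float64)
    return _quadrant_entropy(c[: t + 1, : t + 1]), _quadrant_entropy(c[t + 1 :, t + 1 :])


def select_threshold(cooc: CoocMatrix) -> ThresholdResult:
    """Maximize H(t) = H_BB(t) + H_FF(t) over t in [0, L-2]; ties take the smallest t.

    Computed with 2D prefix sums of the counts and of ``c * log2(c)`` so the
    whole curve costs O(L^2).  A single-level (degenerate) image yields a
    warning and t = 0.
    """
    if cooc.total == 0:
        raise ValidationError("empty co-occurrence matrix")
    c = cooc.counts.astype(np.float64)
    levels = cooc.levels
    with np.errstate(divide="ignore", invalid="ignore"):
        clogc = np.where(c > 0, c * np.log2(np.where(c > 0, c, 1.0)), 0.0)
    csum = c.cumsum(0).cumsum(1)
    esum = clogc.cumsum(0).cumsum(1)
    total_c, total_e = csum[-1, -1], esum[-1, -1]
    t = np.arange(levels - 1)
    s_bb = csum[t, t]
    e_bb = esum[t, t]
    s_ff = total_c - csum[t, -1] - csum[-1, t] + csum[t, t]
    e_ff = total_e - esum[t, -1] - esum[-1, t] + esum[t, t]

    def entropy(s, e):
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(s > 0, np.log2(np.where(s > 0, s, 1.0)) - e / np.where(s > 0, s, 1.0), 0.0)
        return h

    curve = entropy(s_bb, e_bb) + entropy(s_ff, e_ff)
    if np.count_nonzero(cooc.counts.sum(axis=1) + cooc.counts.sum(axis=0)) <= 1:
        warnings.warn("single-level image: threshold selection degenerates to t=0", stacklevel=2)
        return ThresholdResult(t_star=0, entropy_curve=curve)
    t_star = int(np.argmax(curve))
    return ThresholdResult(t_star=t_star, entropy_curve=curve)


def binarize(enh: np.ndarray, t_star: int, levels: int = 256) -> np.ndarray:
    """Label as vein (1) the pixels whose quantized level exceeds ``t_star``.

    Veins carry high accumulated residual values, so the bright side of the
    enhanced image is the positive class.
    """
    return (quantize(enh, levels) > t_star).astype(np.uint8)
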