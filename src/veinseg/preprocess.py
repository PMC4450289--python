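"""Image I/O, region-of-interest localization and local brightness normalization.

Infrared finger images suffer from shading at the image borders (the finger
does not fill the frame) and from non-uniform illumination inside the finger
region.  This module loads 8-bit grayscale rasters, crops the effective
finger region, and applies a local z-score normalization

    u0(x, y) = (r(x, y) - m_r(x, y)) / (sigma_r(x, y) + eps)

where ``m_r`` and ``sigma_r`` are the mean and population standard deviation
of the raw brightness ``r`` over a small box window centred at each pixel.
The z-scored field is then rescaled to [0, 1] so that downstream
quantization and thresholding operate on a bounded non-negative range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ValidationError

__all__ = [
    "ROIRect",
    "LocalStats",
    "load_gray",
    "save_gray",
    "save_mask",
    "load_mask",
    "extract_roi",
    "local_stats",
    "local_zscore",
    "local_normalize",
]


@dataclass(frozen=True)
class ROIRect:
    """A half-open, 0-based rectangle ``[top, top+height) x [left, left+width)``."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValidationError(f"empty ROI rectangle: {self}")
        if self.top < 0 or self.left < 0:
            raise ValidationError(f"ROI rectangle out of bounds: {self}")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.top, self.top + self.height),
            slice(self.left, self.left + self.width),
        )

    def crop(self, img: np.ndarray) -> np.ndarray:
        if self.top + self.height > img.shape[0] or self.left + self.width > img.shape[1]:
            raise ValidationError(f"ROI {self} exceeds image shape {img.shape}")
        return img[self.slices]


@dataclass(frozen=True)
class LocalStats:
    """Per-pixel box-window mean and population standard deviation."""

    mean_img: np.ndarray
    std_img: np.ndarray
    window: int


def load_gray(path) -> np.ndarray:
    """Load a PNG/BMP/PGM raster as a 2D uint8 array.

    RGB input is converted to grayscale by averaging the three channels.
    """
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path!r}: {exc}") from exc
    if arr.size == 0:
        raise ValidationError(f"zero-sized image: {path!r}")
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
        arr = np.round(arr)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2D raster, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255)
    return arr.astype(np.uint8)


def save_gray(img: np.ndarray, path) -> None:
    """Write a 2D array as an 8-bit grayscale raster.

    Float inputs are assumed to live in [0, 1] and are scaled to [0, 255].
    """
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2D image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.round(np.clip(arr, 0.0, 1.0) * 255.0)
    Image.fromarray(arr.astype(np.uint8)).save(path)


def save_float_tiff(img: np.ndarray, path) -> None:
    """Write a real-valued field (e.g. an enhanced image) as 32-bit float TIFF."""
    arr = np.asarray(img, dtype=np.float32)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2D field, got shape {arr.shape}")
    Image.fromarray(arr, mode="F").save(path)


def load_float_tiff(path) -> np.ndarray:
    """Read a 32-bit float TIFF back as a 2D float array."""
    with Image.open(path) as im:
        return np.asarray(im, dtype=np.float32)


def save_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as a {0, 255} grayscale PNG."""
    arr = np.asarray(mask).astype(bool).astype(np.uint8) * 255
    Image.fromarray(arr).save(path)


def load_mask(path) -> np.ndarray:
    """Read a {0, 255} (or any nonzero-is-vein) raster back as a {0, 1} mask."""
    return (load_gray(path) > 127).astype(np.uint8)


def _surviving_run(ok: np.ndarray) -> tuple[int, int]:
    """Longest contiguous True run, preferring the run containing the centre.

    Returns (start, length). Raises if no index survives.
    """
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise ValidationError("no rows/columns survive the ROI cut")
    # split surviving indices into contiguous runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    runs = [(idx[s], idx[e] - idx[s] + 1) for s, e in zip(starts, ends)]
    centre = ok.size // 2
    for start, length in runs:
        if start <= centre < start + length:
            return start, length
    # fall back to the longest run, ties broken toward the centre
    return min(runs, key=lambda r: (-r[1], abs(r[0] + r[1] // 2 - centre)))


def extract_roi(
    img: np.ndarray,
    dark_fraction_threshold: float = 0.5,
    low: int = 10,
    high: int = 245,
) -> tuple[np.ndarray, ROIRect]:
    """Localize the effective finger region of an 8-bit image.

    Rows and columns dominated by near-extreme brightness (shading below
    ``low`` or over-exposure above ``high``) are cut when their fraction of
    such pixels exceeds ``dark_fraction_threshold``; the crop is the maximal
    contiguous central block of surviving rows and columns.  Two independent
    1D cuts are used, one along each axis.
    """
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError(f"expected a nonempty 2D image, got shape {arr.shape}")
    extreme = (arr < low) | (arr > high)
    row_ok = extreme.mean(axis=1) <= dark_fraction_threshold
    col_ok = extreme.mean(axis=0) <= dark_fraction_threshold
    try:
        top, height = _surviving_run(row_ok)
        left, width = _surviving_run(col_ok)
    except ValidationError as exc:
        raise ValidationError(
            f"ROI detection failed ({exc}); rows surviving={int(row_ok.sum())}, "
            f"cols surviving={int(col_ok.sum())}"
        ) from exc
    rect = ROIRect(top=top, left=left, height=height, width=width)
    return rect.crop(arr), rect


def _check_window(window: int) -> None:
    if window < 3 or window % 2 == 0:
        raise ValidationError(f"window must be odd and >= 3, got {window}")


def local_stats(img: np.ndarray, window: int) -> LocalStats:
    """Box-window mean and population standard deviation at every pixel.

    Borders use replicate padding. The variance is computed as
    ``E[x^2] - E[x]^2`` with a clip at zero to absorb roundoff.
    """
    _check_window(window)
    arr = np.asarray(img, dtype=np.float64)
    mean = ndimage.uniform_filter(arr, size=window, mode="nearest")
    mean_sq = ndimage.uniform_filter(arr * arr, size=window, mode="nearest")
    var = np.clip(mean_sq - mean * mean, 0.0, None)
    return LocalStats(mean_img=mean, std_img=np.sqrt(var), window=window)


def local_zscore(img: np.ndarray, window: int = 15, eps: float = 1e-6) -> np.ndarray:
    """Per-pixel z-score against the local box-window statistics.

    Invariant under global affine changes of the input brightness (for
    positive gain, up to the ``eps`` guard on flat regions).
    """
    if eps <= 0:
        raise ValidationError(f"eps must be positive, got {eps}")
    stats = local_stats(img, window)
    arr = np.asarray(img, dtype=np.float64)
    return (arr - stats.mean_img) / (stats.std_img + eps)


def local_normalize(img: np.ndarray, window: int = 15, eps: float = 1e-6) -> np.ndarray:
    """Local z-score normalization rescaled to [0, 1].

    A constant input (zero z-score everywhere) maps to an all-0.5 image by
    convention, so downstream stages always receive a bounded field.
    """
    z = local_zscore(img, window=window, eps=eps)
    zmin, zmax = z.min(), z.max()
    if zmax - zmin < np.finfo(np.float64).tiny:
        return np.full_like(z, 0.5)
    return (z - zmin) / (zmax - zmin)
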