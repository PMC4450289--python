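"""Template-matching mismatch ratio between two vein patterns.

Identification compares a registered vein pattern R against an input
pattern I by sliding the central template of R over I within a displacement
budget and counting label disagreements.  With template region
``R[c_h : h-c_h, c_w : w-c_w]`` the mismatch count at displacement (s, t) is

    N_m(s, t) = sum_{y, x} phi(I(t+y, s+x), R(c_h+y, c_w+x)),

where ``phi(p1, p2) = 1`` iff the two binary labels differ.  N_m is the
minimum over all displacements 0 <= s < 2 c_w, 0 <= t < 2 c_h, and the
mismatch ratio R_m divides it by the total number of vein pixels in the two
compared regions (the best-shift window of I plus the template of R), so
identical patterns give 0 and disjoint ones give 1.

The default geometry (w=212, h=87, c_w=57, c_h=38) reflects finger size and
a ~1 cm positioning allowance in the original capture setup; it scales
proportionally to other image sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ValidationError

__all__ = ["MatchParams", "MatchResult", "phi", "mismatch_count", "match",
           "center_fit"]


@dataclass(frozen=True)
class MatchParams:
    """Matching-window geometry: data size (w, h) and displacement budget (c_w, c_h)."""

    w: int = 212
    h: int = 87
    c_w: int = 57
    c_h: int = 38

    def __post_init__(self):
        if not (0 < 2 * self.c_w < self.w):
            raise ValidationError(f"need 0 < 2*c_w < w, got c_w={self.c_w}, w={self.w}")
        if not (0 < 2 * self.c_h < self.h):
            raise ValidationError(f"need 0 < 2*c_h < h, got c_h={self.c_h}, h={self.h}")

    @classmethod
    def scaled_to(cls, width: int, height: int) -> "MatchParams":
        """Scale the default geometry proportionally to an image of the given size."""
        base = cls()
        c_w = min(max(1, round(base.c_w / base.w * width)), (width - 1) // 2)
        c_h = min(max(1, round(base.c_h / base.h * height)), (height - 1) // 2)
        return cls(w=width, h=height, c_w=c_w, c_h=c_h)


@dataclass(frozen=True)
class MatchResult:
    n_m: int
    s0: int
    t0: int
    r_m: float


def phi(p1: int, p2: int) -> int:
    """Label disagreement indicator: 1 iff one pixel is vein and the other is not."""
    if p1 not in (0, 1) or p2 not in (0, 1):
        raise ValidationError(f"phi expects binary labels, got ({p1}, {p2})")
    return int(p1 != p2)


def _validate_pair(r: np.ndarray, i: np.ndarray, params: MatchParams):
    r, i = np.asarray(r).astype(bool), np.asarray(i).astype(bool)
    for name, m in (("registered", r), ("input", i)):
        if m.shape != (params.h, params.w):
            raise ValidationError(
                f"{name} mask shape {m.shape} != (h, w) = ({params.h}, {params.w})"
            )
    return r, i


def center_fit(mask: np.ndarray, params: MatchParams) -> np.ndarray:
    """Centrally crop and/or zero-pad a mask to the (h, w) matching geometry."""
    arr = np.asarray(mask).astype(bool)
    out = np.zeros((params.h, params.w), dtype=np.uint8)
    rh, rw = arr.shape
    src_r0 = max(0, (rh - params.h) // 2)
    src_c0 = max(0, (rw - params.w) // 2)
    dst_r0 = max(0, (params.h - rh) // 2)
    dst_c0 = max(0, (params.w - rw) // 2)
    nr = min(rh, params.h)
    nc = min(rw, params.w)
    out[dst_r0 : dst_r0 + nr, dst_c0 : dst_c0 + nc] = arr[src_r0 : src_r0 + nr,
                                                          src_c0 : src_c0 + nc]
    return out


def _template(r: np.ndarray, params: MatchParams) -> np.ndarray:
    return r[params.c_h : params.h - params.c_h, params.c_w : params.w - params.c_w]


def mismatch_count(registered: np.ndarray, inp: np.ndarray, s: int, t: int,
                   params: MatchParams) -> int:
    """Label disagreements between the template of R and the window of I at (s, t)."""
    r, i = _validate_pair(registered, inp, params)
    if not (0 <= s < 2 * params.c_w and 0 <= t < 2 * params.c_h):
        raise ValidationError(f"displacement ({s}, {t}) outside the search budget")
    tmpl = _template(r, params)
    th, tw = tmpl.shape
    return int((i[t : t + th, s : s + tw] != tmpl).sum())


def match(registered: np.ndarray, inp: np.ndarray,
          params: MatchParams | None = None) -> MatchResult:
    """Minimum mismatch over all allowed displacements, and the mismatch ratio.

    The search is exhaustive; ties are broken toward the smallest (t, s)
    lexicographically.  The ratio denominator is the vein-pixel total of the
    input's best-shift window plus the registered template region.
    """
    params = params or MatchParams()
    r, i = _validate_pair(registered, inp, params)
    tmpl = _template(r, params)
    th, tw = tmpl.shape
    windows = sliding_window_view(i, (th, tw))[: 2 * params.c_h, : 2 * params.c_w]
    mism = (windows != tmpl).sum(axis=(2, 3))
    flat = int(np.argmin(mism))  # row-major => smallest t, then smallest s
    t0, s0 = divmod(flat, mism.shape[1])
    n_m = int(mism[t0, s0])
    denom = int(i[t0 : t0 + th, s0 : s0 + tw].sum()) + int(tmpl.sum())
    if denom == 0:
        if n_m == 0:
            return MatchResult(n_m=0, s0=s0, t0=t0, r_m=0.0)
        raise ValidationError("degenerate patterns: mismatches without any vein pixels")
    return MatchResult(n_m=n_m, s0=s0, t0=t0, r_m=n_m / denom)
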