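# Methods

## Problem and model

Near-infrared light passes through finger tissue with low absorption but
strong scattering; haemoglobin absorbs it strongly, so veins appear as dark,
low-contrast curvilinear valleys whose cross-sections are Gaussian-like.
`veinseg` extracts the vein network by enhancing *concave* regions of the
intensity surface — places where the image curves upward — without ever
estimating second derivatives directly (ill-posed under noise).

The enhancement minimizes a separable discrete quadratic of Mumford–Shah
type over each small window of the image.  For a window `u0` of side `M`
(vectorized row-major) the row-direction objective is

    J(u) = 1/2 Σ_rows [ u(x,1)² + Σ_y (u(x,y+1) − u(x,y))² + u(x,M)² ]
         + λ/2 Σ (u − u0)²,

whose unique minimizer solves `A u = λ u0` with `A` block diagonal: `M`
identical `M×M` tridiagonal blocks, diagonal `λ+2` (including boundary rows,
which corresponds to implicit zero ghost pixels just outside the window) and
off-diagonals `−1`.  `A` is strictly diagonally dominant, hence symmetric
positive definite and invertible for every `λ > 0`; the suite verifies this
numerically up to `M = 15` in place of a formal proof.  The residual map

    B = λ A⁻¹ − I,    u − u0 = B u0

is precomputed once per `(M, λ)`.  At a concave valley minimum the smoothed
value exceeds the original, so `u − u0` is positive exactly where veins lie.

### Sliding-window accumulation

The window slides over the image; every placement contributes `B·w0` back at
its location and the contributions are summed.  Two observations matter:

- The whole map is linear, so the per-placement loop equals one batched
  matrix product over all window patches (the default `fast` path) and, on
  pixels covered by every placement, a correlation with a single effective
  `(2M−1)×(2M−1)` kernel obtained by summing the entries of `B` at their
  relative offsets.  All three agree within 1e−9 and are tested against one
  another.
- The zero-ghost boundary rows pull each window solution toward zero at the
  window edges, a bias proportional to local brightness.  Accumulated over
  all placements this makes the operator act like a center-surround
  (unsharp-mask) filter with kernel sum ≈ −11 at `M = 9, λ = 1` — which is
  what actually gives the method its band-pass character.  It also means an
  *unpadded* accumulation systematically under-biases the outer `M−1` pixel
  ring; those border values then dominate the global min-max rescale of the
  combined image and squash interior contrast.  The enhancement therefore
  replicate-pads the image by `M−1`, accumulates valid placements, and keeps
  the central `N×N` part, so every output pixel receives the full complement
  of contributions.  `residual_map(..., pad=False)` retains the unpadded
  semantics for inspection and testing.

The procedure runs twice — once on the image, once on its 90°-rotated copy
(back-rotated afterwards) — covering both principal orientations.  Each
directional component is min-max rescaled to [0, 1] (the weakest assumption
that makes them commensurate; a constant component degenerates to zeros),
summed, and rescaled again.  Whether to normalize before or after the back
rotation is immaterial to min-max rescaling; it is done after.

On images up to 6×6 the suite also builds the full non-separable system
(diagonal `λ+4`, four `−1` couplings) and compares its residual with the
separable combination.  Exact equivalence of the two minimizers is *not*
claimed (it is not generally true for quadratic forms); the test quantifies
the gap rather than asserting zero.

## Thresholding

The combined enhanced image is quantized to `L = 256` levels and segmented
by co-occurrence entropy thresholding.  The co-occurrence matrix counts
right- and below-neighbor gray-level transitions (asymmetric, total
`rows(cols−1) + (rows−1)cols`).  For a candidate threshold `t` the
background–background quadrant (levels ≤ t on both axes) and the
foreground–foreground quadrant (levels > t) are each normalized by their own
mass; the threshold maximizes the sum of their Shannon entropies (base 2,
`0·log 0 = 0`, empty quadrant → 0), ties resolved toward the smallest `t`.
Because the criterion sees spatial transitions, two images with identical
histograms but different layouts yield different curves and thresholds —
this is asserted on a block-vs-checkerboard pair.

Two reconstruction choices — per-quadrant (not global) probability
normalization, and exclusion of the off-diagonal transition quadrants — are
conventions of this package; the published description of the underlying
second-order entropy criterion and its later modifications is not specific
enough to pin them down.  Both are isolated in `quadrant_entropies` /
`select_threshold` so alternates can be swapped in.  The whole curve is
computed in O(L²) with 2-D prefix sums of `c` and `c·log₂c`; a brute-force
maximizer serves as the test oracle.

A caveat found during testing: on a noiseless *two-valued* image every
threshold strictly between the two values produces two single-cell quadrants
with zero entropy, so the criterion selects `t* = b` (the upper value)
rather than a separating level.  Real enhanced images are never two-valued
and the criterion behaves well on them; the exhaustive-search oracle agrees
with the implementation in both regimes.

Veins carry high residual values, so pixels with quantized level `> t*` form
the vein class.

## Postprocessing

Binary cleanup is a 1×Y horizontal line dilation (`Y = 5`; veins run along
the finger axis) followed by a 3×3 majority filter — a pixel becomes 1 iff
at least 5 of the 9 cells including itself are 1, cells outside the frame
counting as 0 — iterated to a fixpoint.  The center-inclusive neighborhood
and zero padding are conventions; zero padding is conservative (shrinks
toward background at the frame).  Parallel threshold dynamics can in
principle cycle with period 2; in practice the filter converges, but slowly
eroding structures produced at off-optimal thresholds can need over 100
passes, so the default iteration budget is 500 and exceeding it raises an
error with the count.

## Brightness normalization

For low-quality captures (shading, uneven illumination) the pipeline can
z-score each pixel against its local box-window mean and population standard
deviation (window 15, `σ + 1e−6` guard) and min-max rescale to [0, 1]; a
constant image maps to all 0.5.  The z-score is invariant under global
affine brightness changes.

Normalization is **off by default**.  On high-quality images whose
backgrounds are smooth, the local σ in flat regions falls to the
quantization-noise floor (≈0.4 gray levels), so the z-score amplifies
quantization noise to unit variance; the enhancement operator (kernel ℓ₂
norm ≈ 49) responds to that white noise about as strongly as to a vein
valley of typical z-amplitude, and specificity collapses.  Exactly this
happens on the synthetic database.  High-quality inputs are segmented
without the stage; `normalize=True` (CLI `--normalize`) enables it.

## ROI extraction

The effective finger region is localized by two independent 1-D cuts: rows
and columns whose fraction of near-extreme pixels (< 10 or > 245) exceeds a
threshold (default 0.5) are removed and the maximal contiguous central block
is kept.  This is a reproducible stand-in — the original method is published
only by reference — and can be bypassed with an explicit rectangle or
disabled entirely.

## Synthetic database

No real infrared finger database with ground truth is publicly available,
so evaluation uses generated images: a vein network of random-walk vessel
trees rasterized dark (0) on a light field (1), blurred 3× with a Gaussian
of σ = 1.5 to emulate scattering blur, combined as `0.6·veins + 0.4·bg` with
a background of uniform noise in [0.3, 0.9] smoothed 10× with a wide
(window-31) Gaussian.  Ground truth is the unrasterized network mask.
Defaults chosen here and frozen: 128×192 px frames; 3 seed trees started at
the left edge in stratified horizontal bands (finger veins run roughly
parallel); per-step angular jitter sd 0.05 rad with heading clipped to
±0.7 rad; branch probability 0.015 per step, at most two branches per tree;
stroke half-widths drawn uniformly from [1, 2.5] px (2–5 px wide vessels).
Vein fractions land in 0.08–0.17 and a sample is regenerated (up to 10
times) if it leaves (0.02, 0.40).

What the generator does *not* emulate: photon-transport physics (scattering
point-spread tails, depth-dependent blur), sensor fixed-pattern noise, and
the texture of real tissue backgrounds — the smoothed-noise background is
nearly flat, which is the easiest case for the method.  Passing rates on
this database therefore demonstrate correctness of the pipeline under its
own assumptions (dark Gaussian-like valleys on smooth backgrounds), not
field performance on real captures.  The distortion menu (additive
Gaussian, salt-and-pepper, speckle) probes robustness to acquisition noise
separately.

Per-sample seeds derive from a master seed via `SeedSequence`; the written
manifest is byte-reproducible and a golden digest of a tiny fixed database
anchors the generator against accidental drift.

## Matching

Identification compares a registered pattern `R` and an input pattern `I`
(both `h×w`) by sliding the central template of `R` — rows
`c_h..h−c_h−1`, columns `c_w..w−c_w−1` — over `I` through all displacements
`(s, t) ∈ [0, 2c_w) × [0, 2c_h)` and counting label disagreements; the
mismatch ratio divides the minimum count by the vein pixels of the two
compared regions (the input's best-shift window plus the template).  Ties
break toward the smallest `(t, s)`.  The printed source formulas for the
disagreement indicator and the ratio are typographically corrupted; both
are implemented from their prose definitions (indicator = label inequality;
ratio = division), and the input-side denominator term uses the best-shift
window, matching the indices that appear in the printed sum.  The default
geometry (w 212, h 87, c_w 57, c_h 38) reflects the original capture setup
and ~1 cm of positioning allowance; `MatchParams.scaled_to` scales it
proportionally to other image sizes.  Because the template is a thin
horizontal strip (~13 % of the height), per-image ratios scatter widely
around the database mean.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `window` (M) | 9 | smoothing window side; 81×81 system; matches 2–5 px veins with ~2.6 px blur |
| `lam` (λ) | 1.0 | data-fidelity weight; results vary <1 % across [0.1, 1] |
| `levels` (L) | 256 | gray levels for co-occurrence thresholding |
| `dilate_len` (Y) | 5 | horizontal line element length |
| `majority_max_iter` | 500 | fixpoint budget (slow erosions can exceed 100) |
| `norm_window` | 15 | local-statistics box window (normalization path) |
| `eps` | 1e−6 | σ guard in the z-score |
| `mix_alpha` | 0.6 | vein-image weight in the synthetic composition |

## Problem sizes used in the shipped experiments

The benchmark regenerates 20 images of 128×192 px (master seed 42 unless
overridden), segments each with the defaults above, scores against ground
truth, matches extracted-vs-truth patterns with proportionally scaled
geometry, and sweeps λ ∈ {0.1, 0.25, 0.5, 0.75, 1.0}.  The full run
completes in well under a minute on one CPU via the batched-matmul
residual path.

## Known limitations

- The separable model is an approximation to the joint λ+4 system; the gap
  is quantified, not zero.
- The entropy-criterion reconstruction is one defensible reading of an
  under-specified method; alternates plug into one function.
- Performance collapses when per-pixel noise exceeds roughly level 0.05:
  noise speckle dominates the co-occurrence statistics and the selected
  threshold admits it (see `examples/05_noise_robustness.py`).
- The ROI stand-in cuts only full rows/columns; fingers imaged at an angle
  are not tightly cropped.
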