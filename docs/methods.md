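# Methods

This note records the models, parameter choices and numerical conventions
behind `dermseg`, and what the synthetic-fixture experiments do and do not
demonstrate.

## Coordinate and raster conventions

All rasters are `(row, col)`, 0-based, origin top-left. RGB and gray images
are `uint8` in [0, 255]; HSV keeps hue in degrees [0, 360), saturation in
[0, 1] and value on the integer lattice [0, 255] so intensity transfers are
256-entry lookup tables. Grayscale uses BT.601 luma (0.299/0.587/0.114),
rounded to nearest; the HSV conversion is the standard hexcone model
(delegated to scikit-image) and round-trips within ±1 per channel — the only
quantization anywhere in the pipeline.

## Corner-border removal

Parameters: gray threshold `T = 4` and estimated extent 20 px. Both come
from the method's published calibration on dermoscopy data; both are
config-exposed (`--border-threshold`, `--border-extent`) since other
instruments may leave wider or lighter borders. Borders thicker than the
extent are out of the detector's reach by construction.

Conventions fixed here, where the written procedure leaves slack:

* The diagonal walk moves **inward to the corner** (start at (20, 20),
  decrement both indices); the documented worked example — reject
  144/124 at (5, 5), advance to (4, 4) — fixes this reading.
* Positions with index < 2 cannot supply two diagonal predecessors and are
  defined as "not found".
* The walk uses raw intensities, no smoothing: exactly three consecutive
  sub-threshold diagonal pixels.
* If the top-left search fails, the image is border-free and the other three
  searches are skipped (observable through the search counter). If the
  top-left corner is found but another is not, that corner collapses to the
  image corner, so its side of the inner rectangle is simply not cropped.
* "Detaching" the ring is implemented as a crop to the strict interior of
  the inner rectangle. The crop offset is recorded, and the final mask is
  re-embedded into the original frame with the ring set to background, so
  evaluation always happens at the original geometry. Pixels are never
  resampled.

## Hair removal

The detector is a grayscale blackhat: closing by a structuring element K
minus the image. `K` defaults to a **disk of diameter 17** (config:
`disk`/`cross`/`square`, `--hair-kernel` for the size). Dermoscopy hairs are
1–5 px wide, far thinner than K, so they light up strongly. The disk shape
is a deliberate choice: a cross or square of the same size also fires on the
diagonal arcs of any rounded dark blob (the shell between the blob and its
morphological opening), which makes a hair-free lesion image produce a
non-empty mask; the isotropic disk is silent wherever the outline's
curvature radius exceeds its own, which is exactly the lesion/hair
separation the stage needs. Closing uses nearest-edge padding — reflection
would mirror intensity dips that touch the frame into closable pits and
produce spurious responses on the image border.

Gray-level slicing at 10 turns the contour into the in-paint mask
(`< 10 → 0`, otherwise 255); an all-zero mask short-circuits the stage and
the input is returned bit-identical. The mask is dilated by 1 px before
inpainting to cover anti-aliased hair fringes (disableable); optional
speckle cleaning exists but is off by default.

Inpainting is a fast-marching scheme: the arrival-time map T solves the
unit-speed eikonal equation from the mask boundary (upwind quadratic
update, binary-heap narrow band, ties broken by insertion order — fully
deterministic). Pixels are filled in non-decreasing T. Each fill is the
normalized weighted sum of first-order extrapolations from already-known
pixels in the (2ε+1)² neighborhood, ε = 2:

* `dir` — projection of the unit p−q vector on the boundary normal
  N = ∇T (central differences on T, normalized). Negative projections are
  clamped to 0 so weights stay non-negative; if every neighbor clamps to
  zero (or ∇T vanishes) the scheme falls back to `dst·lev` alone.
* `dst = d₀²/|p−q|²` with d₀ = 1.
* `lev = T₀/(1 + |T(p) − T(q)|)` with T₀ = 1 (the printed form of this term
  has an unbalanced bar; it is read as an absolute difference).

Image gradients at known pixels use central differences restricted to known
pixels (one-sided at the fill front), which makes single-pixel holes exact
on constant and linear images — the first-order exactness the tests assert.
RGB channels share the mask, ordering and weights, and are filled
independently. Only masked pixels are ever written.

## Contrast enhancement

Applied to V only; H and S pass through bit-identical (in HSV space — the
final conversion back to uint8 RGB adds at most the ±1 round-trip step).
The published description of the transfer names three properties (histogram
modification without information loss, log-domain dark lift, nonlinear
re-normalization of the bright tail) but no formulas; the concrete transfer
fixed here is:

1. `h' = (1 − s)·h + s·uniform` with `s = strength` (default 0.5);
2. level weighting `1 + ln(1 + (255 − k)/255)` before the cumulative sum —
   dark levels gain mass, bright levels lose it;
3. the cumulative transfer (mass strictly below each level, so `lut[0] = 0`)
   rescaled to end at 255 and blended toward the identity with weight
   `(k/255)²`, which keeps bright intensities from collapsing; a cumulative
   maximum enforces monotonicity after rounding.

Degenerate histograms (all mass at level 255) fall back to the identity.
The result is always monotone with pinned endpoints, so V-ordering is
preserved. CLAHE and global histogram equalization are available as
ablation alternatives (`--enhance`).

## GrabCut

The published pipeline specifies the initialization (5 %/7 % rectangle,
tri-map with `T_u = ¬T_B`, `T_F = ∅`) but no internals; defaults follow the
original GrabCut formulation: 5 mixture components per model, full
covariances (regularized by 10⁻²·I), γ = 50, 8-connectivity,
`β = 1/(2·mean squared neighbor color distance)`, at most 5 iterations,
convergence when fewer than 0.1 % of the unknown pixels flip. GMMs are
initialized by k-means with a fixed, config-exposed seed (default 0), so
runs are bit-reproducible. The min-cut is solved exactly with igraph's
s–t min-cut on a two-terminal graph; pixels outside the rectangle carry an
effectively infinite foreground cost, so the foreground can never leave the
rectangle.

The data term everywhere — graph capacities and the reported Gibbs energy —
is the negative log-likelihood of the pixel's **best** component,
`−log max_k π_k N_k(z)`. With that convention each sub-step (component
reassignment, per-component ML refit, global min-cut) can only lower the
energy, so the per-iteration monotonicity the tests assert is a theorem,
not an empirical observation. A perfectly uniform image makes both mixtures
collapse to one density; the tie is resolved deterministically to
background (empty lesion) and logged.

`int` in the rectangle rule truncates toward zero; the rule is applied per
axis (height and width separately). The rectangle is half-open: start
inclusive, end exclusive.

## Evaluation

Jaccard `TP/(TP+FP+FN)` and Dice `2TP/((FP+TP)+(TP+FN))` with 255 = lesion.
TN is tracked though unused, so accuracy-style metrics can be added without
re-reading masks. When both masks are empty the pair scores 1.0 with a
warning (NaN on request) — synthetic negative controls would otherwise
crash batch runs. Batch reports are per-image means (the field's dominant
convention), not pooled-pixel ratios.

## Synthetic fixtures

Each fixture is driven by a single `numpy` Generator seeded per spec — no
global RNG state — and composites, in order: skin, lesion, hairs, borders.

* **Skin**: base RGB (205, 160, 145) plus a low-frequency illumination wave
  (amplitude 10) plus spatially correlated texture — white noise low-passed
  with a 5-px Gaussian and rescaled to σ = 3. The correlation length
  matters: pixel-independent noise of realistic amplitude has hair-scale
  dips that the blackhat detector (correctly) flags, and a hair-free
  fixture must produce an empty hair mask.
* **Lesion**: ellipse (aspect ≈ 0.8, random orientation) with low-frequency
  radial wobble (two harmonics, k ∈ {2, 3}, amplitude 0.08 of the radius)
  and a Gaussian-gradated edge (σ = 2.5 px). Real lesion outlines are
  irregular at low spatial frequency and gradated; high harmonics or a hard
  edge would additionally put hair-scale curvature on the outline. Radius
  0.21 of the frame, centered with small jitter — inside the automatic
  rectangle even after the widest (20 px) border crop.
* **Hairs**: 12 smooth curved strokes (sinusoidal bend), width 1–3 px,
  intensity ≈ 60 — dark against skin but far above the border threshold 4,
  so hairs never masquerade as corner borders.
* **Borders**: near-black (intensity 1 < 4) triangular wedges touching the
  four corners, with diagonal depth t ∈ [4, 20] px so the inner-corner walk
  recovers (t−1, t−1) exactly. Non-border content is floored at intensity 4.

Ground truth (lesion, border, hair masks) falls out of the compositing.

What the fixtures do **not** emulate: gel bubbles, rulers and ink marks,
color charts, specular highlights, non-wedge (circular-vignette) border
geometry, multi-lesion frames, and the full color diversity of PH2/ISIC
skin types. Passing the fixture suite therefore demonstrates the pipeline's
internal contracts and the artifact-removal ordering (full pipeline beats a
preprocessing-disabled run on contaminated frames), not clinical-grade
accuracy on real dermoscopy archives.

## Problem sizes

The test and acceptance suites run fixtures at 192×192 (ten seeds per
condition). That size keeps a realistic lesion-to-frame ratio and full
artifact geometry while a complete suite run stays in the low minutes on
one CPU; the pipeline itself is size-agnostic and the generator defaults to
512×512 frames.

## Known limitations

* Small lesions: the fixed 5 %/7 % rectangle encloses mostly skin, and the
  background mixture absorbs the lesion (the documented failure mode on
  small infected regions).
* Borders wider than the configured extent (20 px) are not detected.
* The blackhat detector responds to any structure thinner than K, including
  sharp high-curvature lesion tips; those pixels get inpainted, which
  slightly smooths the outline there.
* The inpainting loop is pure Python with a heap; at default fixture sizes
  it is seconds per image, not milliseconds.
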