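# Methods

This note records the model choices, parameter defaults, numerical details
and limitations of the `hetmap` pipeline. Everything quantitative stated
here is computed by the test suite or by `scripts/acceptance.py`; nothing
is quoted from external measurements.

## Coordinate and field conventions

All coordinates are 0-based with `x` = column, `y` = row; landmark CSVs
store `(id, X, Y)` in that convention. Every transform in the package is a
**backward map**: a stage is a function sending fixed-frame coordinates to
the frame of the image being resampled, and a dense `DisplacementField`
realizes `output(p) = input(p + d(p))` with bilinear sampling. Stages
compose functionally (`ComposedTransform`), so landmarks ride through the
exact same maps as pixels; the moving RGB raster is resampled exactly
twice in a pipeline run (once to feed the FFD, once for the final render).

## Tissue masks

The pipeline needs two masks with different purposes. The
*rough* mask is the biopsy silhouette: Otsu threshold on inverted
luminance, morphological closing with a disk of radius 1% of the shorter
side (min 3 px), hole filling, and removal of connected components below
1% of the largest. The *exhaustive* mask is the bare threshold — every
rip, hole and lumen stays background. There is no canonical recipe for
tissue masking at this level; these parameters are declared defaults, not
fitted values.

## Pre-alignment

Translation is the difference of binary centers of mass (exact under pure
translation). Rotation is a sweep in `step_deg = 10°` increments over
[0°, 360°), rotating the translated moving mask about its own center of
mass with nearest-neighbor sampling (mask-valued, fast), scoring
`|A ∩ B| / sqrt(|A||B|)` and breaking ties toward the smaller angle. The
sweep cannot do better than ±5°; the affine stage absorbs the residual.

## Affine stage

Six parameters (2×2 matrix + offset of the backward sampling map),
mean-squared error on 0/1 mask images, 3-level Gaussian pyramid
(coarse→fine, factor 2). The regular-step rule uses the classical
settings: initial step 6.25e-2, minimum step 1e-5, gradient tolerance
1e-4, relaxation 0.8, at most 100 iterations per level. Two numerical
choices matter:

* the descent runs in a **scaled parameter space** — matrix entries at
  unit scale, translations divided by the image diagonal — so one step
  length is meaningful for all six parameters;
* a trial step that increases the MSE is reverted and the step relaxed,
  which makes the accepted-MSE sequence nonincreasing and guarantees the
  returned fit is never worse than the identity.

## Diffeomorphic demons

The per-pixel force is `v = (Im−If)∇If / (|∇If|² + (Im−If)²)` with the
central-difference gradient of the fixed image and a zero force where the
denominator underflows (‖v‖ ≤ ½ everywhere by AM–GM). Under the
backward-sampling convention the SSD-descent direction is the *negated*
force; the update is exponentiated by scaling-and-squaring (guaranteeing
a positive-Jacobian step) and composed into the accumulated field, which
is then Gaussian-smoothed with σ = 1.0 px (diffusion-like regularization;
a fluid-like option on the update is exposed via the config but off by
default). Three pyramid levels, 100 iterations per level, masks smoothed
with σ = 0.5 to define gradients; the best-SSD field is kept, with an
early stop after 10 consecutive SSD increases.

## B-spline free-form deformation

The warp is the 2-D tensor product of cubic B-splines over a control
lattice with uniform spacing (default [50, 50] px) covering the image
plus a one-cell margin; moving one control point affects only a
4-spacing × 4-spacing area. The cost is

```
C(ϕ) = mean_ROI log(|I_M(p + T(p)) − I_F(p)| + ε)  +  λ · C_smooth(ϕ)
```

with ε = 1e-6 (the log is −∞ at exact equality), λ = 0.01, and
`C_smooth` the standard thin-plate bending energy — the mean over a
4-samples-per-cell lattice of `T_xx² + 2T_xy² + T_yy²`, second
derivatives analytic from the spline (zero for constant and affine
warps). The similarity uses grayscale luminance; color only drives
segmentation. Sign conventions for this cost family are inconsistent across the
literature (a literal minus on a lower-is-better similarity would reward
misalignment); this package *minimizes* `C_sim + λ·C_smooth`.

Two numerical devices make this cost optimizable:

* **Luminance presmoothing** (σ = 1 px): the log metric weights each
  pixel by `1/(|diff|+ε)`, so pixel-level acquisition noise at matched
  pixels otherwise dominates the gradient with random sign.
* **Graduated non-convexity**: the additive floor is annealed
  (0.1 → 0.03 → 0.01 → 1e-3 → 1e-6) with warm starts. At a large floor
  the metric is quasi-L1 and informative at a distance; the final stage
  is the exact objective. Each stage runs L-BFGS-B (quasi-Newton) with
  analytic gradients assembled through the spline weights, at most 70
  iterations and a 1e-6 relative-decrease stop. The returned grid is the
  best iterate under the exact (ε = 1e-6) objective, so the returned
  cost can never exceed the cost of the zero grid.

Without the annealing, descent from ϕ = 0 stalls in a noise-induced local
minimum even when the true warp scores strictly better — this was checked
explicitly before adopting the scheme. A multi-resolution control-grid
schedule is deliberately out of scope (a single [50, 50] grid is used).

## Stain classification

Brown (DAB, positive) and purple (hematoxylin) are both red–blue
mixtures; in the joint (R, B) histogram they straddle the `R = B`
diagonal, so the pixel rule is: background if `min(R, G, B) ≥ 200` or
outside the exhaustive tissue mask; else positive if `R > B`, counterstain
otherwise (ties conservatively to counterstain). A radius-1 morphological
opening removes isolated positive speckle. Tiling (default 512×512) is a
memory strategy only — the tissue mask is computed once on the full
raster, so tiled output is bit-identical to untiled. Stain-vector color
deconvolution is intentionally not used: it assumes Beer-Lambert
linearity that IHC chromogens violate.

## Evaluation metrics

* `rTRE`: per-landmark Euclidean error / image diagonal; aggregates are
  the mean and median over image pairs of the per-pair median, and the
  mean of per-pair maxima.
* Robustness: fraction of landmarks whose rTRE *strictly* improved vs the
  unregistered state (there is no standardized definition of a
  "successfully registered" landmark; strict improvement is this
  package's definition).
* Confidence map: pixelwise sum of registered exhaustive masks;
  percentages are normalized over the union support (count ≥ 1), so they
  sum to 100 and the top level is complete overlap.
* Hausdorff: symmetric max of the two directed distances, computed with a
  Euclidean distance transform (the directed forms are exposed too); the
  test suite keeps a brute-force pairwise-distance oracle.

## Synthetic fixtures

The generator emulates what the pipeline actually faces, with exactly
known ground truth:

* a smooth blob silhouette (randomized radial harmonics) with **two
  texture octaves** (Gaussian scales 12 px and 4 px) — real sections
  carry structure at several scales, and the local stage's similarity
  needs that signal;
* **interior lumina** (30–45 small ellipses): glandular/vascular openings
  that the exhaustive mask preserves and the rough mask fills. They are
  what gives the confidence map headroom between outline-level (global)
  and interior-level (local) registration;
* two-stain IHC coloring: purple counterstain (B − R = 50) and brown
  positive blobs (R − B = 80) at nominal intensity, additive Gaussian
  channel noise σ = 6 inside the tissue, flat near-white background
  (level 245) — separable but non-trivial classes;
* per-section deformation `x ↦ R_θ(x + ffd(x) − c) + c + t` with
  translations up to 20 px, rotations up to 25°, and a control grid of
  amplitude 8 px at 64 px spacing; 86 landmarks per section (a typical
  ANHIR-style annotation density) transported
  **analytically** through the forward map while the raster is resampled
  through its numerically inverted map (fixed-point on the local warp) —
  truth stays exact to machine precision;
* acquisition artifacts applied after warping and recorded as masks:
  rips (thin erased chords), holes (erased ellipses), folds (darkened
  bands), with per-section rates 0.5 / 0.5 / 0.3.

Default problem size is a 4-section 256×256 stack — small enough that the
full pipeline registers a stack in well under a minute, large enough for
3 pyramid levels and a meaningful [50, 50] control grid.

What the fixtures do **not** emulate: nuclei-level texture, stain
intensity drift between sections, section-to-section morphological
evolution (each section is a deformed copy of one template), and
full-resolution image scale. Passing tests therefore demonstrate correct
recovery of known deformations and correct metric arithmetic under
realistic noise and artifacts — not clinical-grade performance on real
slides, where inter-section biology adds an irreducible error floor.

## Limitations

* Pyramidal WSI containers are not parsed; users supply extracted
  renditions at working resolution (typically 5–10% of full resolution).
* Stain classification runs at working resolution in the pipeline; the
  full-resolution path is a documented extension.
* The rotation sweep assumes the silhouette has a correlation-unique
  orientation; a nearly circular biopsy resolves to 0° by tie-break and
  relies on the affine stage.
* Registration quality is data-driven: unstained, torn or near-blank
  sections fail per-section and are recorded in the run report rather
  than aborting the stack.
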