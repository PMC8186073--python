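# Methods

This note documents the model behind `amsmw`, the parameter choices that
matter, the synthetic data the tests run on, and the numerical decisions a
maintainer would want spelled out.

## Pipeline model and assumptions

The pipeline assumes a single hypoechoic (darker than surround) lesion
roughly centred in a user-drawn rectangular ROI, imaged with multiplicative
speckle and possibly low contrast. Everything downstream is deterministic
image processing; there is no training phase and no randomness outside the
phantom generator.

**Contrast weighting.** The inverted enhanced image is multiplied by the
union (pixelwise maximum) of five equal-covariance Gaussians whose standard
deviations are half the RROI extents. Union-by-maximum keeps the five
peaks at equal height; summation would triple-weight the centre. The five
centres are the rounded RROI centre and its four integer translations by
(round(σ_h), round(σ_w)) — i.e. the RROI corners — so that the grid
attains every peak exactly and the field is exactly symmetric under 180°
rotation about the centre. The product is rescaled linearly to [0, 255]
before the openings so the downstream 1–255 threshold sweep is meaningful;
the weighting itself produces arbitrarily small values.

**Side-window filter.** Defaults: box kernel, radius 3, 5 iterations
(config keys `swf.*`). Box windows have exact step-edge preservation: a
window lying flat on one side of an edge has mean exactly equal to the
pixel value. Window means are computed as weighted sums divided once by
the weight total, so box means of integer-valued images are exact and the
argmin over windows is stable; ties go to the first window in the order
L, R, U, D, NW, NE, SW, SE. The Gaussian kernel option uses σ = r/2.
Borders replicate edges everywhere in the pipeline, to avoid spurious dark
rims that would bias the threshold sweep.

**CLAHE.** `clahe.clip_limit` is expressed as a multiple of the uniform
histogram bin height (default 2.0, i.e. clip at twice the average count)
on an 8×8 tile grid; internally it maps onto scikit-image's normalised
clip scale as `clip/256`. A constant image is returned unchanged — there
is no contrast to redistribute — and a tile grid coarser than the image
falls back to a single tile with a warning.

**Morphological snake.** The evolution uses three sub-steps per iteration:
balloon, attraction, curvature smoothing. Decisions that required
experimentation rather than transcription:

- *Balloon structuring element*: the 3×3 square (unit Chebyshev ball). With
  the 4-connected cross the attraction term re-adds pixels as fast as the
  balloon removes them and the curve reaches a fixed point far outside the
  lesion (measured at ≈4.7× the lesion area on the default phantom); the
  square front outruns that noise and the snake converges.
- *Smoothing order*: one SI∘IS pass per iteration, with the composition
  order alternating between iterations (SI∘IS, then IS∘SI). A fixed order
  systematically biases the area because IS is extensive and SI
  anti-extensive.
- *Edge-stopping field*: `g = 1/sqrt(1 + α|∇(G_σ * J)|²)` on the [0,1]
  normalised image, α = 20000, σ = 2. α sets the depth and width of the
  stall band (`g ≤ θ`) around a true edge. At α = 1000 the band is too
  shallow and the shrinking front erodes straight through speckled lesions;
  at α = 5000 most lesions segment but wide lesions with weak lateral
  edges are still tunnelled through where the band thins below the
  1-pixel-per-iteration front step. α = 20000 keeps the band ≥ 2 px for
  every phantom preset without stalling the balloon in the speckled
  background after SWF smoothing.
- *Balloon sign and threshold*: v = −1 (the circle shrinks onto the
  lesion), θ = 0.3. The shrink-from-enclosing convention requires the
  initial circle to contain the lesion; see limitations.
- The SI/IS segments are the four collinear 3-pixel segments through the
  origin (horizontal, vertical, two diagonals) — the four orientations a
  3-pixel straight line can take on the lattice.

**Adaptive dispatch.** The initial circle radius and iteration count come
from the RROI extents (h, w): radius `w − 20` when `min(h, w) ≥ 20`, else
`w − 10`; 250 iterations when `h ≥ 1.5 w` (tall lesions), else 120.
Boundary cases are closed non-strictly so the dispatch is total, and the
radius is clamped below by `max(round(0.3 min(h, w)), 1)` so boxes
narrower than the subtrahend still produce a circle. The thresholds 20/10
are in pixels of RROI extent. `ams.dispatch_override` forces a specific
(radius, iterations) pair.

**Marker function and marked area.** Structuring elements: 15-px-radius
disk (B1), 15-px-wide square (B2), 25-px-radius disk for the closing.
Binary erosion/dilation/closing by disks is computed with the exact
Euclidean distance transform, which is identical to a structuring-element
sweep (verified against a brute-force oracle in the tests) but linear-time
in the image size; square elements use min/max filters. The closing pads
the frame so border-adjacent structures close like interior ones. Pixels
outside the image count as background.

**Watershed.** The flood surface is the radius-1 morphological gradient of
the segmentation input `J_N` — flooding raw intensity would conflate
brightness with boundary evidence. The lesion seed is the marked-area
component nearest the RROI centre; the background seed is a 3-px border
band minus a 5-px safety dilation of the lesion seed. Flooding is
4-connected; plateau ties resolve in first-in-first-out order, which on a
constant surface assigns each pixel to its nearest marker with ties to the
lesion label.

**ARD scoring and the fast path.** The average radial derivative is the
mean, over contour pixels, of the central-difference gradient projected on
the unit outward direction from the RROI centre. It is evaluated on the
*enhanced* image (original polarity, lesion dark), not on the inverted
weighted image J: on J the lesion is bright, so its true boundary would
minimise rather than maximise the outward derivative. Candidates are
swept over thresholds 1–255 in full mode; fast mode evaluates the single
calibrated threshold 96 (`select.fast_threshold`), falling back to the
nearest available threshold, and to the AMS mask when no threshold yields
a marked area. Ranking ties break toward the calibrated threshold, then
the lower threshold.

## Synthetic phantoms: what they emulate and what they do not

Each phantom is a star-shaped lesion (ellipse with a seeded low-order
harmonic boundary perturbation, harmonics 2–6, default relative amplitude
0.15) of mean intensity 55 on a background of 150, softened by a σ = 1
blur, with optional bright 2–3 px calcification spots, an optional
posterior enhancement/shadow band, and unit-mean multiplicative gamma
speckle (default standard deviation 0.25, lightly correlated by a σ = 0.5
blur). The default canvas is 160×160 px with semi-axes (22, 28), jittered
±10% (and the centre ±4 px) per seed; the RROI is the ground-truth
bounding box plus a 10 px margin, mimicking a radiologist's loose box.
These values were chosen once as a plausible mid-contrast BUS-like regime —
lesion/background ratio ≈ 0.37 and speckle comparable to what the SWF can
suppress — and the presets (`tall`, `wide`, `small`, `calcified`,
`shadowed`, `enhanced`) exist to reach the four dispatch branches and the
named confounds.

The generator is an appearance model, not an acoustic simulation: no beam
geometry, no depth-dependent attenuation or focusing, no anisotropic
resolution cell, and its speckle is uncorrelated with structure. Passing
the phantom suite therefore demonstrates internal correctness and
robustness to the modelled confounds, not clinical-grade accuracy; scores
on real BUS data will be lower and should be measured with the
`eval-batch` tooling on a real annotated dataset.

## Numerical choices

- Images are float64 in [0, 255]; masks boolean; coordinates 0-based
  (row, col); RROI bounds half-open.
- The RROI centre rounds to the nearest pixel with ties toward the lower
  index (a discrete seed is needed; the exact centre falls between pixels
  for even extents).
- Binarisation is inclusive (`intensity ≥ th`).
- Contours are traced by Moore-neighbour walking with Jacob's stopping
  criterion plus a repeated-state guard: on 1-pixel-thick shapes the walk
  can re-enter the start pixel from a different backtrack than the
  artificial initial one, and the deterministic (pixel, backtrack) state
  repeating closes the cycle instead. Contour filling uses 4-connected
  hole filling, which an 8-connected pixel chain seals.
- The largest 4-connected component is kept when a mask must be a single
  object (contour extraction, AMS output); the lesion is assumed to be the
  dominant object.
- Degenerate inputs fail loudly as `DomainError`s (empty masks, blank
  images, out-of-range thresholds, RROIs smaller than 5 px per side), with
  two documented fallbacks: a collapsed snake returns its initial circle,
  and a threshold sweep with no marked area returns the AMS mask; both
  warn.

## Problem sizes

The test suite and the acceptance script run on 160×160 phantoms — 20
segmentations end-to-end plus a 10-phantom speckle-free snake-only batch —
and on 24×24 to 128×128 fixtures for the operator-level oracles. A fast-
mode segmentation takes ≈0.5 s and a full 255-threshold sweep ≈5 s on one
CPU core at this size.

## Known limitations

- The shrinking balloon requires the initial circle to enclose the lesion.
  The dispatch ties the radius to the RROI *width*, so for markedly tall
  lesions (`h > 1.5 w`) in tight boxes the circle cannot cover the lesion
  tips and the snake may collapse onto a fragment; the pipeline then falls
  back to the AMS mask or the marker evidence. Wide and near-isotropic
  lesions are unaffected. A growing-balloon variant would cover this case
  but is a different evolution regime.
- The fast path's threshold 96 is a calibration constant; on data whose
  `J_M` histogram differs substantially it should be re-derived (sweep a
  sample with `--mode full` and inspect the chosen thresholds) and set via
  `select.fast_threshold`.
- Single lesion per RROI; multi-focal masses need one box per lesion.
- Pixel units throughout; no physical spacing or probe calibration.
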