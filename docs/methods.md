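# Methods

`mycometry` quantifies the growth of a filamentous fungus (the model
white-rot species *Phanerochaete chrysosporium* on *Miscanthus x
giganteus* substrate fractions) from tiled, time-lapse brightfield
micrographs, without destroying the culture. The package has two halves:
an analysis pipeline (stitch → filter → threshold → measure → fit) and a
ground-truthed generator of synthetic image series used to validate the
pipeline, since no micrographs from the emulated experiment were
deposited.

## The measurement model

A droplet of spore suspension is absorbed into a grey nitrocellulose
membrane laid on an agar medium; the membrane is imaged repeatedly on a
motorised stage as overlapping tiles (10 % overlap, 1.3 × 1.3 µm²/px,
8-bit grayscale). All objects visible at time 0 are counted as spores
(mean area ≈ 560 µm²). Growth is then summarised by four statistics:

1. **Germination.** The percentage of germinated spores at each
   observation time, and the interval rate
   `((pct₂ − pct₁)/100 · N₀)/(t₂ − t₁)` in spores/h, where `N₀` is the
   time-0 object count and the first interval starts from (0 h, 0 %).
2. **Coalescence.** `100 · N(t)/N(0)`, the percentage of initially
   counted 8-connected objects still distinct at time *t*. Growing germ
   tubes bridge neighbouring microcolonies, so this percentage can only
   fall; it is a sensitive early-growth signal while objects remain
   countable.
3. **Surface occupation.** The summed area of foreground pixels, in µm²
   (pixel count × 1.69 µm²). Its growth is exponential over two windows
   (23–29 h, 3 frames; 29–52 h, 4 frames); the rate µ (h⁻¹) is the OLS
   slope of ln(area) against time, with R² computed on the log scale.
4. **Radial expansion.** Once coalescence is complete the mycelial mat
   is a single colony; its diameter — taken here as the Feret diameter
   (maximum pairwise distance between foreground pixel centres) of the
   largest object — grows linearly, and the speed *v* (µm/h) is the OLS
   slope over the late window.

Fraction additivity: for cultures A (agar control), B (whole substrate),
C (soluble), D (unwashed solid), E (washed solid), the control-subtracted
final areas are compared as `(C−A)+(D−A)` vs `B−A`; near-equality means
the fungus uses soluble and solid fractions additively.

The printed summary tables of the emulated study are bundled in
`mycometry.data` and serve as the canonical inputs for the reproduction
analyses (per-frame totals are rebuilt as mean object area × object
count). Note two internal inconsistencies of those printed tables that
bound any reproduction: the integer germination percentages imply rates
that differ from the printed ones by up to 2 spores/h for two intervals
(the original rates evidently used unrounded percentages), and the
printed coalescence percentages for cultures C and E differ by 1 point
from the counts in the same table (duplicate-averaged raw data). The
reproduction tests therefore compare at the precision the tables print —
one unit in the last printed digit — except for the germination-rate
check, which keeps its conventional ±1 spores/h and is expected to fail
for exactly those two intervals.

## The processing chain

Order: stitch → median filter → CLAHE → rolling-ball background
subtraction → mean+maximum filtering → automatic threshold. All images
are 8-bit; each step records its parameters in a provenance list.

* **Stitching.** Tiles are placed at their nominal grid offsets;
  optional refinement corrects each tile against its already-placed
  neighbour by the phase-correlation peak over the nominal overlap
  window (search ±`max_shift_px`, default 5). A peak is accepted only if
  the aligned overlaps correlate (Pearson r ≥ 0.5); otherwise the
  nominal offset is kept with a warning. Overlaps are feather-blended
  (weights ramp linearly from the tile edge); a last-tile-wins mode
  exists for exactness testing.
* **Filters.** Median (radius 2 px), CLAHE (contextual region 1/8 of the
  image, slope limit 2.0; `kernel_frac=1` with unlimited clip reduces to
  global histogram equalisation, computed in closed form), rolling-ball
  subtraction (base radius 50 px), then a 3×3 mean and a 3×3 maximum
  filter. Radii and clip values are declared defaults — the emulated
  workflow names the operations but not their parameters.
* **Adaptive ball radius.** A rolling ball smaller than the largest
  bright object climbs into its plateau and carves it apart. Because the
  colony grows from ~25 µm spores to a millimetre-scale mat within one
  series, the chain pre-segments each frame (Otsu on the current image)
  and enlarges the ball to the largest object's bbox half-width plus a
  margin. For large radii the background is estimated on a shrunken copy
  (factor ≈ radius/10) and resized back, which is indistinguishable for
  structures much smaller than the ball; a linear illumination ramp has
  no curvature, so any ball radius removes it.
* **Thresholding.** Yen's maximum-correlation criterion for the time-0
  frame (very sparse foreground), Otsu's between-class variance
  afterwards. Both are computed on the fixed 0–255 histogram with ties
  broken toward the lowest qualifying value, and foreground is
  `image > t`; both are verified against exhaustive 256-candidate search
  and cross-checked against scikit-image's implementations. A constant
  mosaic yields an empty mask with a warning rather than an error.

## Morphometry

Objects are 8-connected components (visual connection in the 2D mosaic),
labelled in deterministic raster order. Per object: pixel and µm² area,
centroid, bbox, ellipse axes, eccentricity (clipped to [0, 1); collinear
degenerate objects would otherwise return exactly 1). A particle-size
floor (default 100 µm² in the pipeline, well below the ~560 µm² spore)
discards residual noise specks, as in standard particle-analysis
practice. Objects touching the image border are kept. Germination is
scored morphologically: area ≥ 2× the resting-spore baseline (median
object area of the time-0 frame) or eccentricity ≥ 0.85 — a germ tube
elongates an object long before it doubles its area. Both thresholds are
exposed configuration.

## The synthetic generator

`SimConfig` defaults describe the emulated study conditions: 687 spores
(the observed counts ranged 645–715) of lognormal area (mean 560 µm²,
CV 0.25) placed uniformly in a 3.5 mm-radius droplet mark centred in a
12288 px field; frames at 0, 23, 26, 29, 46.5, 49.5, 52 h; 5×5 tiles
with 10 % overlap; a ±15 % diagonal illumination gradient and Gaussian
sensor noise (σ = 6 grey levels). Spores are placed with a minimum gap
(13 µm) so the time-0 objects are separable — the emulated experiment
counted its deposited spores as distinct particles.

Germination lags are lognormal; the default moments (mean 19.7 h,
sd 4.8 h) are moment-matched to a fast-germinating culture profile
(78/90/94 % cumulative germination at 23/26/29 h). Germinated spores
emit one germ tube at a uniform heading; tips advance at
`tip_speed_um_h` with Gaussian heading diffusion and branch as a Poisson
process per tip (side branches at ≈60°), with branching suppressed above
a tip-population cap (crowding surrogate). The kinetic defaults
(16 µm/h, 0.18 branches/tip/h) are calibration choices, set once so that
coalescence into a single object completes between 29 h and 46.5 h as in
the emulated endpoint; they are not measured values. Growth sub-steps
align to an absolute 0.5 h grid, so advancing in one call or several
consumes the random stream identically; one seeded generator drives all
draws and fixed seeds give bit-identical series.

Rasterisation draws spore discs and 3 px-wide hyphal polylines on the
pixel grid; the ground truth carries the true mask, 8-connected object
count, occupied pixels and germinated count per frame, plus per-spore
lag times. Because geometry only grows, masks nest over time — object
counts are non-increasing and occupied area non-decreasing by
construction, which the tests assert.

What the generator does **not** emulate: 3-D growth into or through the
membrane, nutrient-field coupling between growth and substrate, hyphal
avoidance/tropism, spore clumping, focus drift, vignetting beyond a
smooth ramp, and stage-position error beyond rigid per-tile jitter.
Passing tests therefore show that the measurement chain is correct for
flat, well-focused, rigidly tiled imagery with additive noise — not that
it is robust to every artefact of real micrographs.

## Problem sizes and numerical choices

Tests and the acceptance script run density-preserving shrinks of the
study-scale configuration (`scaled_study_config`): linear dimensions
scale by a factor, spore count by its square, preserving the
nearest-neighbour spacing that controls coalescence timing. The suite
uses scales 0.08–0.18 (3–22 spores, 1000–2200 px fields); the acceptance
script uses 0.15. Sub-step 0.5 h; reflective field boundaries; germ
tubes snap to the sub-step grid, so single-tip kinematics are exact to
one sub-step.

Degenerate inputs: constant images raise on thresholding (handled as
empty masks at the pipeline level, with a warning); empty masks have
undefined colony diameter (error) and zero occupied area; exponential
fits reject non-positive areas and windows with fewer than three frames;
two-point linear fits report R² = 1 by convention.

## Known limitations

* The mean+maximum smoothing dilates the segmented mask by roughly the
  filter radius, so chain-measured areas overestimate the true mask by a
  boundary band (≈1.7× for 3 px-wide hyphae at these scales). The
  emulated workflow shares this bias; cross-culture comparisons and
  log-slope rates are unaffected (a constant area factor shifts only the
  intercept), which is why the noise-free exactness check bypasses the
  smoothing filters — on clean input they only trade exactness for
  robustness.
* Coalescence timing at small simulation scales is noisier than at study
  scale (few spores), so tests assert the qualitative pattern (distinct
  objects at 29 h, one object by 46.5 h) rather than specific counts.
* The radial-expansion speed of a simulated colony approaches twice the
  tip speed only once branching has populated the front; fits over
  windows that include the sparse early phase underestimate it.
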