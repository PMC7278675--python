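# Methods

## Problem setting

A fried-dough crumb imaged by two-channel confocal microscopy contains
three phases: fluorescently stained solid matrix (one channel),
penetrated frying oil stained in the frying bath (second channel), and
empty pores (dark in both channels).  The quantities of interest are
area fractions (porosity, penetrated oil), per-pore shape descriptors,
the crust's surface roughness expressed as a box-counting index, and
regressions linking the image metrics to solvent-extraction oil
content across formulations (bran type × bran level × dough/batter).

Images are treated as 8-bit, two-channel, 2-D frames with an isotropic
physical pixel size (default 2.768 µm at 512 × 512 px).  Non-8-bit
input is min–max rescaled with a warning.  Maximum-intensity projected
2-D images are assumed; no z-stack handling.

## Segmentation

Conventions, fixed once and used everywhere:

* thresholds are integers in [0, 255] computed on the 256-bin
  histogram; *foreground* means strictly greater than the threshold;
* tie-breaks select the lowest qualifying bin, so outputs are
  deterministic;
* noise cleaning is a morphological opening: `n_erode` erosions then
  `n_dilate` dilations (default two of each) with a 3 × 3 square
  structuring element, outside-of-frame counting as background.

**Otsu** maximizes the between-class variance
`w₀w₁(µ₀ − µ₁)²` over all 255 cut points.  **Triangle** draws a line
from the histogram peak to the outermost occupied bin of the longer
tail and picks the bin of maximal perpendicular distance; it suits the
strongly unimodal histograms of sparse-phase channels.  Both are
implemented directly (vectorized) rather than delegated, because the
binning, strict-greater foreground and lowest-bin tie-break
conventions must be pinned for reproducibility; tests verify them
against exhaustive brute-force scans.  A useful check on the Otsu
convention: for *dense* symmetric histograms, inverting the image maps
the threshold to `255 − t − 1`.  For sparse histograms the variance is
constant on plateaus between occupied bins and the lowest-bin
tie-break picks opposite plateau ends under inversion, so the identity
holds only in the dense case.

**Phase combination rule**: the cleaned oil-channel foreground is the
oil phase; the cleaned matrix-channel foreground *minus* oil is the
solid phase; the remainder is empty pore.  Oil wins where both
channels are bright, because red signal reports penetrated oil
regardless of matrix co-location.  The three masks partition the frame
by construction.  A constant channel under automatic thresholding is
treated as all-foreground if its value is non-zero (saturated signal)
and all-background otherwise; only two channels constant at the same
value are rejected as indistinguishable.

**Wand selection** (tolerance flood fill, 4- or 8-connectivity,
tolerance 0–5, default 2) is provided as the programmatic counterpart
of interactive pore picking; the automated pipeline path is
`classify_pixels`.

## Morphometry

Pores are connected components (default 4-connectivity, matching the
wand convention) of the void mask.  Components below `min_area_px = 4`
pixels are dropped as residual noise.  Border-touching pores are kept
and flagged, not excluded.

The perimeter is the length of the particle's outer boundary polygon
traced by marching squares at the 0.5 level and smoothed with a
circular 3-vertex moving average.  This choice is a calibration
decision: raw pixel-edge counting overestimates smooth boundaries
(digital disk circularity ≈ 0.5), Crofton-type estimators are
calibrated for smooth curves but overestimate the circularity of
polygons (square ≈ 0.88).  The smoothed polygon gives a digital disk
(r = 50 px) circularity 0.98 and an axis-aligned square π/4 + 0.01,
satisfying both calibration points; an elongated ellipse (2:1) agrees
with its analytic circularity to < 0.01.  Circularity is capped at 1.
Solidity is area over convex-hull area.  "Pore size" means the
equivalent circular diameter `√(4A/π)`; histograms default to 25 µm
bins over 0–500 µm (frequencies in %, summing to 100).

Porosity and POia are pure pixel-count ratios of the phase masks, so
`POia ≤ porosity` and `porosity + solid fraction = 100 %` hold exactly
on every input.

## Crust roughness

The crust image (per-pixel maximum over channels, when two are
present) is binarized with Otsu, opened, and reduced to a Sobel edge
map.  For binary input the edge set is the skeletonized non-zero
gradient band — a single-pixel closed midline.  Skeletonizing keeps
the edge set symmetric under image inversion (edges of the mask equal
edges of its complement) and close to the geometric boundary; note the
8-connected chain *count* of a digital circle underestimates its arc
length by ~10 %, an orientation bias inherent to pixel counting, which
is irrelevant to the box-count slope.

Box counting uses non-overlapping r × r cells anchored at the image
origin over the ladder (2, 3, 4, 6, 8, 12, 16, 32, 64), counting cells
containing at least one edge pixel; partial cells at the right/bottom
edges are included, and no multi-offset minimization is applied,
matching common plugin behaviour.  Because consecutive ladder sizes
are not nested (4 → 6), counts are guaranteed non-increasing only for
connected boundary sets — the operation's input domain — not for
arbitrary sparse speckle, where a border-straddling pixel pair can
occupy more large boxes than small ones.

The dimension is `D = −slope` of the least-squares line through
`(log r, log N(r))`, using all sizes with positive counts (zero-count
sizes are dropped with a warning; at least three are required).  The
reported index adds one dimension, `FD = 1 + D`, to represent the
roughness of the imaged 3-D surface: a straight edge measures
2.00 ± 0.01, an order-6 triadic Koch curve 2.23 (analytic
1 + ln4/ln3 ≈ 2.262), a filled frame 3.00.  The Koch calibration uses
order 6 at 729 px so that every ladder scale lies inside the curve's
scaling regime; at order 5 the 2–4 px boxes already resolve individual
segments and the estimate drops to ~2.18.

## Regression stage

Relationships between porosity, POia and POsox are summarized per
formulation group (bran type × product type, six formulation means
each: control plus five bran levels) by OLS cubic polynomials with R²
computed on the fitting data.  Fits use a standardized predictor basis
internally and report raw-basis coefficients; at least five points and
four distinct predictor values are required.  Because the
predictor/response orientation of published "A vs. B" labels is
ambiguous (and demonstrably inconsistent between published columns),
`build_relationship_matrix` always fits both orientations of each of
the three pairs and reports all six R² per group.  Degenerate fits
(constant predictor) are flagged, not raised, in the batch report.

The shipped fixture `data/table1_metrics.csv` contains the published
formulation means (porosity, POia, POsox, crust FD) for oat- and
wheat-bran dough and batter.  Recomputing the cubic fits from these
printed means reproduces the published R² values to ~0.01 (e.g.
0.8333 vs 0.8432 for porosity vs POia in oat-bran dough); the residual
gap is consistent with the published fits having used unrounded or
replicate-level data, which the printed tables do not provide.  Fits
are therefore asserted within ±0.02 of the published values.

## Synthetic data

`generate_crumb_micrograph` emulates what the segmentation stage must
cope with, not the physics of frying:

* **Pores** are rotated ellipses with lognormal equivalent diameters
  (median 60 µm, log-sd 0.6, truncated to [20, 475] µm — the upper
  bound matching the observed crumb pore-size range) and minor/major
  axis ratios uniform on [0.3, 0.9], giving mean circularity well
  below 1.  Placement is dart throwing below a solid crust band
  (default 40 px ≈ 110 µm): non-overlapping until sampling stalls,
  then overlapping to emulate coalesced gas cells (`overlap="auto"`;
  `"never"` restores strict non-overlap and raises when the target is
  unreachable).  Non-overlap alone saturates near ~55 % coverage, so
  high-porosity crumb (up to ~80 %) necessarily enters the coalesced
  regime, as real batter crumb does.
* **Consistency with segmentation**: the pore mask is closed (two
  iterations, 3 × 3 square), which removes solid slivers thinner than
  the segmentation's fixed two-step opening can preserve; by duality
  the solid phase is then exactly opening-stable.  Oil bodies are
  likewise kept opening-stable per pore component.  The stored truth
  map is therefore exactly the structure a noise-free rendering
  depicts, and noise-free classification recovers it essentially
  pixel-exactly (≥ 99.4 % agreement; porosity within ~0.5 pp; POia
  exactly).  Placement is closing-aware near the target, so the
  realized porosity lands within ~1 pp of the requested value.
* **Oil assignment** fills pores nearest the crust first (greedy by
  centroid depth, with an exact partial top-up), and the oil channel
  intensity decays exponentially with depth below the crust band
  (decay length 80 px ≈ 220 µm, floor 140 so the signal stays
  unambiguous), reproducing the crust-to-crumb oil gradient seen in
  stained sections.
* **Rendering**: matrix level 200 on solid, oil 140–230, background 0;
  additive Gaussian noise (default sd 8 grey levels, a mild speckle
  consistent with confocal photon noise after projection; Poisson
  available) before clipping and 8-bit quantization.

What the generator does **not** emulate: partial-volume boundary
intensities, uneven illumination, staining heterogeneity, out-of-focus
light, or physically realistic wall-thickness distributions.  Passing
recovery tests therefore demonstrates correctness of the measurement
chain on well-posed three-phase images, not robustness to every
confocal artefact; real-data use should inspect per-image thresholds
(logged by the pipeline) and the cleaned masks.

`generate_fractal_crust` synthesizes textures by spectral shaping of
white noise with an isotropic `|f|^−(H+1)` amplitude; the roughness
parameter in [0, 1] maps linearly to a Hurst-type exponent
H = 1 − 0.85 · roughness.  Smaller H yields more convoluted Otsu level
sets and a higher measured FD: over 5 levels × 10 seeds the Spearman
correlation between the parameter and pipeline FD is ≈ 0.95.  The
mapping is monotone but not metrically calibrated — equal parameter
steps do not produce equal FD steps.

`generate_koch_edge` rasterizes the triadic Koch curve (4ⁿ segments at
order n; width must be ≥ 3ⁿ px) as the analytic calibration object.

## Numerical and degenerate-input choices

* Constant images raise a degenerate-histogram error from the
  threshold estimators; callers decide fallbacks (the classifier's
  constant-channel convention above; the edge mapper returns an empty
  mask).
* Empty particle tables are valid results (zero count, NaN means), not
  errors; empty edge masks yield all-zero box counts with a warning
  and an insufficient-data error at the fitting stage.
* The log–log fit uses natural logarithms (the slope is base
  invariant) and `numpy.polyfit`; the cubic stage solves the
  standardized least-squares problem rather than raw normal equations
  for conditioning.
* All randomness flows through `numpy.random.default_rng(seed)`;
  every generator is a pure function of (parameters, seed), and batch
  outputs embed the package version, a configuration hash and the seed
  in their CSV headers.

## Problem sizes used in validation

Unit and acceptance tests run the recovery grid (porosity
{20, 40, 60, 80} % × POia {5, 10, 20} % × 3 seeds, noise-free and at
the default noise level) on 256 × 256 px frames with a 16 px crust
band, a size at which placement statistics and boundary effects are
representative while a full grid completes in well under a minute; the
acceptance script uses the same frame size with 2 seeds per cell.
Crust monotonicity uses 256 px textures, 5 roughness levels × 10
seeds.  The generator's 512 px default is exercised by the worked
example and the simulation CLI.

## Known limitations

* 2-D sections only; no pore-network topology (interconnected / blind
  pore classification is out of scope).
* The published per-pore tables and pore-size peaks from the original
  micrographs cannot be recomputed without those images; published
  image-derived values serve as plausibility bands (porosity 52–82 %,
  POia 4.6–19.7 %, crust FD 2.55–2.76, pore sizes 0–475 µm), and this
  package's regression stage reproduces the published R² pattern from
  the printed means.
* Circularity of very small particles (a few pixels) is dominated by
  quantization and is capped at 1; interpret shape descriptors for
  pores ≳ 10 px across.
* CZI files are not parsed; convert to TIFF upstream.
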