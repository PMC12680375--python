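# Methods

This note records the models, conventions, parameter choices and known
limitations behind `pcpquant`, in the order data flows through the package.

## Conventions

Pixel coordinates are (row, col), origin top-left. All reported angles use
the mathematical convention — counter-clockwise from the image horizontal —
so images oriented with the proximo-distal axis horizontal read 0° for
proximo-distal structures. Every orientation in the package (polarity axis,
cell long axis, junction orientation, microtubule direction) is **axial**,
period 180°; statistics on axial data double the angle, operate on the
circle, and halve the result. Directional (360°) readouts are out of scope.

## Tissue graph (geometry module)

A label mask is parsed with 4-connectivity for cell regions and
8-connectivity for the membrane skeleton. A skeleton (zero) pixel adjacent
to exactly two cell labels belongs to that pair's **junction**; a pixel
adjacent to three or more labels is a **vertex** and belongs to no
junction, so junction statistics are not contaminated by triple points.
Junction orientation is the chord between the traced endpoints of the
skeleton segment (degree ≤ 1 pixels under 8-connectivity); for a curved
junction this end-to-end axis is the intended summary. Single-pixel
junctions fall back to the normal of the line joining the flanking cell
centroids and are flagged low-confidence.

The **membrane band** over which fluorescence is measured is the junction
skeleton dilated by a square of width 3 px (configurable), clipped to the
two flanking cells. 3 px spans the apico-lateral junctional signal at
typical sampling without swallowing cytoplasm; the measured band width is
not otherwise constrained by the data the package consumes.

Cell geometry is the inertia-equivalent ellipse of the pixel region:
semi-axes a = 2√λ₁, b = 2√λ₂ of the coordinate covariance (exact for a
filled ellipse), eccentricity e = √(1 − λ₂/λ₁). Orientation is flagged
undefined for e < 0.05: near a = b the direction is meaningless while e
itself — a square-root of an axis ratio — is hypersensitive to pixel-level
shape noise (a rasterised regular hexagon fits at e ≈ 0.2 although its
axis ratio is within 2% of 1). Downstream code treats undefined-orientation
cells as circles (φ = 0, b = a).

## PCA polarity

The polarity statistic is described in the README. Two implementation
choices matter and are deliberate:

- **Equal-angle sector pooling.** Building one pseudo-point per membrane
  *pixel* makes the second-moment matrix depend on how densely the
  rasterised membrane samples each direction: a diagonal membrane band
  contains up to |cos α| + |sin α| ≈ 1.4 times more pixels per unit length
  than an axis-aligned one, which biases recovered angles by ~10° on
  regular meshes. Pixels are therefore pooled into 72 equal angular
  sectors (5°) around the centroid, each non-empty sector contributing its
  mean intensity as one pseudo-point. The statistic is then invariant to
  sampling density, and the eigen angle still equals the axis of maximal
  directional variance of the pseudo-points (checked against a 0.1°
  brute-force scan).
- **Moments about the origin**, not about the pseudo-point mean: unipolar
  and bipolar membrane distributions then register on the same axis, and a
  uniform ring gives exactly M = 0.

Intensities are normalised by the cell's mean sector intensity, making M
invariant under global intensity scaling. A cell is measured only with ≥ 8
membrane pixels covering ≥ 8 sectors; membranes uniform to a coefficient
of variation < 10⁻³ return M = 0 with an undefined angle. The reported
angle is the principal axis in the shape-normalised frame rotated back by
the cell orientation φ. For strongly elongated cells whose polarity axis
is oblique to the cell axis, the unit-circle normalisation shifts angular
positions (the axis-scaling part of the map is not undone — only the
rotation is), so recovered angles on such tissues carry a geometry-driven
offset of order 10° at e ≈ 0.87; magnitudes are unaffected, which is the
sense in which the measurement is geometry-independent. Background is
subtracted as a single per-image constant, either supplied or estimated as
the mean intensity of eroded cell interiors.

The timer **stable fraction** is r = mean(mKate2 − bg) / mean(sfGFP − bg)
over the same membrane band; r is undefined (flagged) when the denominator
is not positive after subtraction.

Per-wing aggregation maps each cell to (M cos 2ψ, M sin 2ψ) and averages
component-wise; orthogonal axes cancel, as axial data require. Hotelling's
T² compares groups of such per-wing vectors (pooled covariance, F
transform with (2, n_A + n_B − 3) df; one-sample variant with (2, n − 2)).
Whether to vectorise on raw or doubled angles is a genuine convention
choice; the doubled-angle form is used throughout because the underlying
measurement is axial, and this is stated prominently since polarity is
often drawn as full-circle arrows.

## Microtubule orientation

Images are first contrast-normalised by percentile clipping (0.5% lowest
pixels to black, 0.5% highest to white, linear in between). Gradients come
from the separable 5×5 Sobel pair (binomial smoothing [1 4 6 4 1] ×
central derivative [−1 −2 0 2 1]); texture orientation is the gradient
direction + 90°, weighted by gradient magnitude, accumulated into 1° bins
over [0°, 180°) per cell. Cells are eroded by one pixel before
accumulation so membrane-edge gradients do not contribute, and cells
smaller than 25 px after erosion are excluded.

**Von Mises fit and MTSD.** The normalised histogram is fitted by weighted
least squares with a two-component mixture: a uniform floor plus an axial
Von Mises (doubled angles, mean 2μ, concentration κ). The uniform
component absorbs unoriented gradient weight — filament ends, crossings,
noise — so the Von Mises parameters describe the oriented texture itself.
The main microtubule direction is μ; **MTSD is the circular standard
deviation of the fitted curve**, (180/π)·√(−2 ln A(κ̂))/2. Fitting the
curve rather than taking raw circular moments matters quantitatively: on
rendered line textures the raw moment estimate of dispersion is inflated
roughly twofold by the unoriented contamination, while the curve fit
recovers the generating dispersion to ~10%. The raw moment value is still
reported (`mtsd_moment_deg`) because it is defined for every non-empty
distribution and varies monotonically with the generating concentration.

A cell is **excluded** when the optimiser fails, the raw resultant length
vanishes, the fitted curve explains less than half of the histogram's
squared deviation from uniformity (R² < 0.5 — the operational meaning of
"unfittable"), or MTSD ≥ 90°. Near-uniform textures reliably fail the R²
rule (typical R² ≲ 0.2); weakly oriented textures (κ ≲ 1) are often
excluded too, which is honest: at realistic per-cell filament counts they
are statistically indistinguishable from uniform at the single-cell level.

Aligned average profiles shift each cell's distribution so its modal bin
sits at 0°, normalise to unit sum, and average within eccentricity bins
(defaults 0.750 ± 0.025 and 0.800 ± 0.025). Display histograms use 9 bins
over 0–180°, optionally mirrored to the full circle (counts are conserved
before mirroring).

## Boundary rows and junction classes

Rows are layered by breadth-first search over junction adjacency from the
source (overexpressing) set: row 0 shares a junction with the source, row
k with row k−1. Vertex-only (diagonal) contact does not propagate — rows
are junction-sharing shells. Boundary k is the junction set between rows
k−1 and k. The boundary axis defaults to the length-weighted circular mean
orientation of boundary-0 junctions (robust to gently curved boundaries);
a fixed axis may be supplied. A junction's class is decided by its acute
angle to that axis: ≤ 45° **horizontal**, otherwise **medio-lateral**,
with the tie at exactly 45° documented as horizontal. Intensity summaries
report, per row 0–3 and class and per named boundary, the mean over
junctions of each junction's background-subtracted mean band intensity;
empty combinations are omitted rather than reported as zero. Vein or
otherwise unwanted cells can be excluded by leaving them out of the
analysis set; no automatic detection is attempted.

## Synthetic tissue generator

The generator provides the ground truth that validates every stage; its
defaults are the package's reference conditions.

- **Mesh**: nearest-seed (Voronoi) regions of a hexagonal lattice with
  per-seed uniform jitter of 0.12 × spacing (a visibly disordered but
  connected epithelium; 0 gives crystalline hexagons), cell spacing 28 px.
  A square-lattice option exists for scenarios that need junctions at
  exactly 0°/90°. Anisotropy is applied as a global affine x-stretch
  evaluated in the virtual isotropic frame, so a stretch a/b = s yields
  cells of eccentricity √(1 − 1/s²) at orientation 0° exactly — a
  closed-form target for geometry recovery. The membrane skeleton is one
  pixel (label differences to the right/down neighbour).
- **Junction intensities**: I = B + A·sin²(α − ψ̄), with α the junction
  orientation and ψ̄ the axial mean of the two flanking cells' polarity
  axes, painted uniformly on each junction's membrane band (overlaps near
  vertices are averaged). Junctions perpendicular to the polarity axis are
  brightest, giving a 2:1 perpendicular:parallel contrast at A/B = 1 —
  the magnitude of junctional enrichment the analysis must detect. The
  sin² profile is a modelling choice; the real angular intensity profile
  of a polarised cell is not prescribed by the measurements the package
  reports.
- **Polarity patterns**: `uniform` (one axis ψ₀), `swirl` (axes tangent to
  circles about a vortex, emulating locally ordered but globally swirled
  polarity), and `boundary` repolarisation: cells in row r ≤ L rotate from
  ψ₀ toward the boundary-parallel axis by the fraction 1 − r/(L+1), deeper
  rows keep ψ₀. The graded profile encodes a repolarising influence that
  decays with distance from the boundary over the propagation length L,
  so the first row repolarises fully and deeper affected rows partially.
  Source cells are rendered unpolarised-bright (B + A on all junctions),
  emulating uniform overexpression.
- **Timer**: mKate2 = f × sfGFP before background and noise, one stable
  fraction f per dataset. This is sufficient to validate a ratio
  estimator; it is not a maturation-kinetics model.
- **Noise**: i.i.d. additive Gaussian per channel plus a constant
  background. Noise levels quoted as percentages mean σ as a fraction of
  the junction baseline B. No optics/PSF model, no Poisson statistics by
  default, no mechanical tissue dynamics.
- **Filaments**: per cell, 120 anti-aliased line segments of length 30 px
  (about one cell diameter), centred at random cell pixels, clipped to the
  cell mask, with axial orientations drawn from a Von Mises on doubled
  angles (κ = 0 → uniform). The density emulates a near-continuous apical
  network; sparse short segments would make even perfect Von Mises
  textures look half-uniform to any estimator, because line ends and
  crossings contribute unoriented gradient weight.

What passing recovery tests on this generator does **not** show: accuracy
on real microscopy with depth-dependent background, bleed-through,
segmentation errors, curved/partial cells, or intensity profiles unlike
sin². Absolute intensity values are in arbitrary units throughout; only
ratios and angles are interpreted.

## Reference conditions and problem sizes

The validation suite and `scripts/acceptance.py` use: ~200–270-cell
tissues for polarity recovery (uniform ψ₀ = 25°, A/B = 1, 5% noise;
border-clipped cells excluded from recovery statistics, as their geometry
is truncated), ~100-cell tissues for microtubule scenarios (texture with
analytic axial SD 15°, i.e. κ ≈ 4.23), a 506-cell mesh for row layering,
2 000 replicates of 8-vs-8 wings for Hotelling calibration, and a 192-cell
boundary scenario with propagation length L = 1. These sizes give stable
statistics in seconds per scenario on one CPU.

## Numerical details

- Eigen-decomposition of the 2×2 second-moment matrix is closed-form;
  λ₂ is clamped at 0 against rounding.
- κ is recovered from a resultant length by inverting the Bessel ratio
  I₁/I₀ with Brent's method on exponentially scaled Bessels; the mixture
  fit bounds κ ∈ [10⁻³, 10⁴] (MTSD ≈ 0.3° at the upper bound) and
  evaluates bin probabilities by 3-point averaging so near-degenerate
  peaks are resolved at 1° bins.
- Ties: junction class at exactly 45° → horizontal; quadrant split at
  ±45°/135° → left-open, right-closed intervals.
- Degenerate inputs are flagged, not guessed: all-zero intensities,
  sub-minimal pixel counts, undefined references, non-positive timer
  denominators, singular covariances (the error names the degenerate
  direction), axial means of exactly cancelling axes.
- Determinism: every stochastic operation takes an explicit seed; identical
  inputs and seeds give bit-identical images and tables.
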