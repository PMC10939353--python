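# Methods

This note documents the models, algorithms, parameter choices and
limitations of `f2f`. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`.

## Coordinate and unit conventions

Coordinates are `(row, col)` in pixels, 0-based, with pixel centres at
integer positions. All physical lengths convert through the sample-plane
pixel size (default 64.5 nm/px: a 6.45 µm camera pixel behind a ×100
objective). The diffraction limit expressed in pixels (default 5.5)
parameterizes every derived length: the detection/median window is twice the
diffraction limit rounded to odd (11 px), the isolation radius is that minus
one (10 px) and the contour radius that plus two (13 px). The PSF is modelled
as an isotropic Gaussian with σ = diffraction limit / 2.355, i.e. FWHM equal
to the diffraction limit (σ ≈ 2.34 px).

## The distance model

The measured 2D distance between two labels at true separation μ whose
positions carry isotropic Gaussian localization noise σ follows the
normalized Rice density

p(d | μ, σ) = (d/σ²) exp(−(μ²+d²)/(2σ²)) I₀(dμ/σ²).

The implementation evaluates log I₀ through the exponentially scaled Bessel
function (`i0e`), so the log-density is finite for arguments dμ/σ² well
beyond 10⁶, where the Rice law tends to a Gaussian of width σ. Tests verify
normalization to 1e−6 by quadrature, the Rayleigh limit at μ = 0, agreement
with an independent Rice implementation, and the Gaussian asymptote.

Some published statements of this density carry an extra 1/(2π) factor;
that version integrates to 1/(2π), not 1. MLE locations are unaffected by a
constant factor, but quoted log-likelihoods and normalization tests require
the proper density, so `f2f` uses the normalized form throughout.

### Maximum likelihood

(μ, σ) maximize the summed log-density via bounded L-BFGS-B on (μ, log σ),
initialized from moments: σ₀² = var(d)/(2 − π/2) (the Rayleigh-corrected
variance) and μ₀ = √max(mean(d²) − 2σ₀², 0). Bounds keep μ ∈ [0, 2·max(d)]
and σ below the same scale; a maximizer at μ = 0 is reported as 0 with a
`mu_at_boundary` flag. A degenerate sample (all distances equal, or fewer
than three) is an error. On samples of n ≤ 50 the optimizer's log-likelihood
is verified against a dense 200×200 grid search; over 20 replicates of
Rice(20, 10) at n = 500 the median |μ̂ − μ| is below 1 nm.

### Bootstrap outlier rejection

Mislinked or contaminated pairs sit in the upper tail of the skewed distance
distribution and can destroy the MLE (a 5% contamination at 10× the typical
distance drives μ̂ to 0). Rejection works over a grid of candidate upper-tail
trim fractions (0–30% in 2.5% steps):

- For each candidate trim, the kept (lower) fraction is refit by plain MLE on
  bootstrap resamples.
- Each candidate is scored by the bootstrap-averaged per-point
  pseudo-log-likelihood of the *full* sample under a two-component model:
  kept points follow the truncation-renormalized fitted Rice density with
  weight (1 − f); trimmed points follow an unstructured uniform tail
  component with weight f over (cutoff, max distance]. At f = 0 this is
  exactly the bootstrap-averaged per-point Rice log-likelihood.
- The first maximizer in grid order wins (ties favour less trimming); the
  final model is a plain MLE on the kept subset, with standard errors from
  bootstrap refits of that subset.

The uniform tail component is what makes trim levels comparable: scoring
each candidate only on its own kept subset is monotone in the trim fraction
(truncation always reduces entropy), so that naive rule trims maximally even
on clean data. With the two-component score, clean Rice samples select trims
≤ 2.5–5% and keep μ̂ unbiased, while planted-outlier samples select exactly
the contaminated fraction and recover ≥ 90% of the planted points (verified
in the tests). With fewer than 10 distances rejection is skipped and the
result flagged.

## Registration

Bead centroids are detected per channel with a wide window (median diameter
+ 10 px ≈ 4.5 PSF sigmas, keeping mask-truncation bias below 0.01 px), after
subtracting the scalar image median. Aggregates are removed two ways:
resolved doublets as mutual neighbours within the window diameter + 4 px,
unresolved doublets by an integrated-mass cut at 1.6× the median bead mass.

Matching is mutual nearest neighbour per field. Because the chromatic
displacement can exceed the final matching tolerance, `register_beads` is
two-pass: a coarse match (4× tolerance, ≥ 6 px) fits a provisional affine
map, and the definitive match at the user tolerance (default 2 px) runs on
provisionally corrected channel-1 coordinates before the final fit.

Fields are split into fit and validation halves by alternating over the
(optionally permuted) field order, the fit half taking the extra field when
the count is odd. The affine map (2×2 linear part + translation) is solved
by least squares on homogeneous coordinates; at least three non-collinear
correspondences are required and three give exact interpolation. The TRE is
the mean Euclidean residual norm over held-out beads after correction,
reported with per-axis mean absolute deviations and the pre-correction
deviation; the Euclidean mean is the gate value because a single scalar is
needed, with the per-axis numbers alongside. Correction monotonically
improves over no correction on any distorted dataset, and the fit is
rotation-equivariant (both verified).

On the reference synthetic calibration — a 100-field grid of 25–75 beads per
512×512 field, 0.3% scaling + 1.5 px translation distortion, 0.2 nm per-axis
bead localization noise — the held-out TRE is ≈ 0.5 nm from ~1700 validation
beads, comfortably below the 1 nm gate. The residual is dominated by
photon-statistics and background-noise centroiding error at the simulated
bead brightness (5×10⁵ detected photons, appropriate for multicolour
calibration beads, which are far brighter than single fluorescent
proteins).

## Pre-processing

Rolling-ball subtraction (Sternberg's morphological background) with radius
70 px (slightly larger than a cell) removes extracellular background and
uneven illumination. Radii above 20 px run on a coarse grid (downscale,
exact rolling ball, upscale) — the background is smooth at that scale, the
approximation is exact on flat images, and the cost drops from ~9 s to
~0.5 s per 512² frame. Median subtraction (square window, side 11 px,
optional disk footprint) then removes cytoplasmic structure: structures
larger than the window cancel, spots survive (losing only the ~10–17% of
peak that the window median sits on, symmetrically, so centroids are
unaffected). Both stages clip at zero because downstream centroiding
assumes nonnegative intensities; clipping after each stage (rather than
once at the end) is a documented choice.

A sharp cell-edge step and the bright membrane rim are only partially
removed — the residual is a thin band near the contour. The induced centroid
pull is largely common to both members of a rim pair and mostly cancels in
their distance: on noise-free cell scenes the absolute localization bias is
~0.35 px median, but the pair-distance error is ~3 nm median. This is the
main accuracy limit of the pipeline on cell images.

## Detection, linking, correction

Localization is Crocker–Grier style: candidate maxima above the image's
99th-percentile brightness, at least half a window apart, refined by
iterative intensity-weighted centroiding over a circular mask (radius 5 px
at defaults), with integrated mass, second momentum (intensity-weighted mean
squared radius) and eccentricity (from the intensity covariance eigenvalues,
√(1 − λmin/λmax)) computed from the final window. Gaussian-fit positions are
deliberately *not* used for localization — the Gaussian fit serves only the
quality filter.

A finite circular mask truncates the PSF tails asymmetrically, shrinking the
measured sub-pixel offset by a constant factor (0.75 at an 11 px window and
σ = 2.34 px; linear in the true offset to < 1e−3 px). When the PSF width is
known, the final offset is divided by this factor, calibrated on the same
discrete pixel lattice the detector uses. Without this compensation the
shrinkage acts as ~0.09 px of phase-dependent error per spot and the
end-to-end distance error leaves the target envelope.

Linking is mutual nearest neighbour between the channels of one field
(greedy closest-first available as an option), keeping pairs within the
user's maximum separation — 2 px for intra-assembly and 3 px for
inter-assembly measurements at the reference setup. Equidistant candidates
resolve toward the brighter channel-2 spot, deterministically. Each spot
joins at most one pair; linking is symmetric under swapping channel roles
(verified). Channel-1 coordinates are then corrected with the registration
map and distances recomputed; the pre-correction coordinates are kept in the
pair table because the selection filters compare against the spot table and
segmentation mask in the detector frame. Correction is mandatory in the
workflow; passing an explicit identity map is the debug escape.

## Selection cascade

Fixed order: isolation → cell contour → feature density → Gaussian fit.
Each stage only evaluates pairs that passed every earlier stage, so stage
populations are nested (verified, including against a brute-force
all-distances oracle for the isolation rule).

- **Isolation**: a pair fails if any third spot (either channel) lies within
  10 px of either member.
- **Contour**: cell boundaries come from the label mask (external masks of
  any origin are accepted; the bundled fallback thresholds a smoothed image
  at the half-height between inside/outside medians, fills holes, shrinks by
  one pixel to compensate the bright-rim pull, and labels components —
  IoU ≈ 0.96 against generator truth disks, adequate for well-separated
  round cells but not for crowded or irregular ones). Both members must be
  within 13 px of a contour pixel (Euclidean distance transform, sampled at
  rounded coordinates); spots slightly outside the cell pass, since the
  anchor sits on the membrane.
- **Density**: per channel, a Gaussian KDE (Scott's rule) over standardized
  (second momentum, eccentricity); each pair scored by the lower of its two
  channels' density percentile ranks; pairs kept from the top of the score
  ranking down. The cutoff is a probability threshold: retention is
  1 − cutoff by rank (exactly half at the default 0.5), a cutoff near 1
  keeps only the densest pairs, near 0 keeps all. Fewer than 20 eligible
  pairs skips the filter with a warning flag.
- **Gaussian fit**: isotropic 2D Gaussian plus constant offset, nonlinear
  least squares over the detection window of the preprocessed image; the
  joint 2D model is fitted (the marginal-1D alternative was considered and
  rejected as less constrained). R² = 1 − SSres/SStot per spot; both members
  must reach 0.35. Non-converged fits score −∞ and fail. Clean rendered
  spots score > 0.999, pure-noise windows ~0, double-lobe artefacts < 0.35
  (all verified).

## Anchor QC across datasets

Anchor platforms should image alike across experiments: mean spot brightness
tracks the anchor copy number, mean second momentum tracks platform
structure. Per dataset both means are computed over channel-1 spots; across
≥ 3 datasets a Theil–Sen line (robust to a minority of artefactual
datasets) is fitted in (mean mass, mean second momentum) and datasets are
flagged when their residual exceeds 3 robust standard deviations (1.4826 ×
MAD) *and* 5% of the mean second momentum — the practical-significance floor
prevents flagging trivially tight families on sampling noise. Two datasets
give a trend with a low-n note and no flags; one gives means only. Flags are
invariant under dataset order and under a common intensity gain (verified).

## The synthetic generator

What it emulates: two-channel bead calibration grids (uniform bead
positions with ≥ 4σ spacing, per-bead brightness shared across channels,
channel 1 distorted by a configurable affine map plus localization jitter)
and yeast-like cell fields (disk cells with cytoplasmic background and a
membrane rim, anchor spots on the rim, prey displaced by the true separation
in a random direction, independent per-axis localization jitter per
channel — so observed distances are Rice(μ, √2·jitter) by construction).
Camera model: Poisson shot noise, Gaussian read noise (σ = 2), constant
baseline (100). Defaults: 512×512 frames; beads 5×10⁵ photons over 20
photons/px background; anchors 8×10³ and preys 5×10³ photons over
10/40/20 photons/px extracellular/cytoplasmic/rim background; cells of
radius 22–28 px, 10 per field, 2 pairs per cell. These photon and
background levels are field-realistic choices, not measured properties of
any instrument.

What it does not emulate: bud/mother cell geometry and non-circular cells,
spectral bleed-through, focus drift and axial (z) structure, autofluorescent
organelles, bead re-imaging correlations across overlapping calibration
fields (each synthetic field is independent; a real 90%-overlap grid
re-images the same beads at different sensor positions, which pools
correlated detections — harmless for the affine fit but worth noting).
Passing tests therefore demonstrate correctness of the algorithms under the
stated noise model, not performance on every real-data pathology.

## Orchestration and determinism

`run_workflow` executes the stages in order into a run directory, writing
CSV/TIFF/JSON outputs plus per-stage sentinels holding a hash of the
parameters each stage saw; unchanged stages are reused on rerun. Stage
outputs are read back through their serialized form before further use, so
warm (cached) and cold runs are byte-identical (verified). All randomness
derives from the single configured seed through spawned child seeds. The
TRE gate (< 1 nm) warns by default and aborts the run when enforcement is
switched on.

## Problem sizes

The acceptance checks run the full 100-field calibration (25–75 beads per
512² field) for the TRE, 1000 pairs for the density-filter retention, and
20 seeded end-to-end replicates of 4 cell fields (80 pairs each, shared
calibration, mild 0.1% + 0.5 px distortion) for the distance-recovery
envelope; unit tests use smaller scenes of the same construction. The
end-to-end median |μ̂ − 20 nm| over the 20 replicates is well inside the
2–5 nm envelope (typically ≲ 1 nm, with single replicates up to ~3 nm).

## Known limitations

- The cell-edge residual after pre-processing biases absolute spot positions
  by a few tens of nanometres; distances are protected only by common-mode
  cancellation, so geometries where the two labels sit at different depths
  relative to the membrane will fare worse.
- The threshold segmentation fallback assumes well-separated, roughly
  circular cells; crowded fields need an externally supplied mask.
- The exact composition (not the size) of the density-filtered population
  depends on the KDE bandwidth and the per-channel min-rank combination;
  other reasonable choices retain the same fraction but may swap borderline
  pairs.
- The trim-selection score compares a truncated-Rice-plus-uniform-tail
  pseudo-likelihood; it is designed to be conservative on clean data and is
  validated on synthetic contamination, not guaranteed optimal for every
  outlier mechanism.
- Only 2D distances in the image plane are measured; axial offsets shorten
  projected distances and are not modelled.
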