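# Methods

## The measurement being modeled

An intact inner colonic mucus layer excludes bacteria-sized particles:
1-µm fluorescent beads sedimented onto explanted, live intestinal tissue
stay at the mucus surface, while a defective layer lets them sink toward
the epithelium.  Two readouts quantify this barrier:

1. **Normalized penetrability** — from a two-channel confocal z-stack
   (calcein-stained tissue, fluorescent beads), the axial distance from
   the tissue surface to each bead is measured, binned, and reduced to the
   area under a normalized frequency curve (details below).
2. **Mucus growth rate** — with black 10-µm beads marking the mucus
   surface in a perfused chamber, thickness is read with a
   micromanipulator every 15 min at up to five locations for up to
   45 min; the growth rate is the slope of thickness over time.

Cohort context (lean vs genetically obese ob/ob littermates, housed
separately or together; normoglycemic vs diabetic NOD mice) adds
metabolic covariates — body weight, fasting glucose, fasting insulin,
HOMA-IR — and the group/correlation statistics used on such panels.

## The penetrability statistic

Given per-stack distances `d_i` (µm, bead minus local tissue surface
height):

1. **Histogram.** Uniform half-open bins `[j·b, (j+1)·b)` from 0 past the
   maximum distance; default bin width `b = 5 µm`, chosen comparable to
   the axial sampling of a 20x water-immersion stack and coarse enough to
   give a stable modal bin.  Distances below the detected tissue surface
   (possible with noisy surfaces) are clamped into the first bin and
   reported, never dropped.
2. **Max normalization.** `f = counts / max(counts)` removes the
   arbitrary absolute bead number per stack.
3. **Surface alignment.** The mucus surface is the modal bin — beads
   accumulate at the surface of any layer with a surface-retaining
   component.  Ties break toward the outermost (largest-distance) bin,
   and *statistical* ties are treated like exact ones: every bin whose
   count is within 5% of the maximum is a tie candidate.  Without this,
   a near-flat distribution (a fully penetrated layer) would anchor at
   whichever bin multinomial noise happens to favor, and the statistic
   would collapse unpredictably; 5% covers the count fluctuations at the
   bead numbers used here (hundreds to 10^6 per stack) without affecting
   any clearly peaked distribution.
4. **Crop.** Bins above the surface (beads floating in the buffer) are
   dropped and counted.  The curve ends at the deepest occupied bin:
   trailing empty bins carry no observation and are trimmed, which makes
   an impenetrable layer score exactly 0 and makes the statistic exactly
   invariant to shifting all distances by whole bins.
5. **AUC.** Trapezoidal integral of `f` over depth (physical µm, bin
   centers).  A single-point curve scores 0.  Integration over µm rather
   than bin index affects the absolute scale only, not group contrasts.

Bead-derived **thickness** is the arithmetic mean of all `d_i` (the
literal "average tissue–microbead z-axis distance"; no bead subset is
privileged).  Per mouse, the scalar readout is the **median** of its
stacks' AUCs, and the display curve is the pointwise median of the
stacks' normalized curves on the union depth grid with zeros beyond each
curve's extent — matching the "median bead frequency distribution"
display convention.

### Closed-form expectation

`expected_penetrability` evaluates the exact large-n expectation of the
statistic under the generative mixture (below): per-bin probability
masses are computed analytically and pushed through the same
normalize/align/crop/integrate rules.  It assumes zero surface jitter
and a thickness that is an integer multiple of `b` (so the surface spike
sits exactly on a bin edge).  With half-open bins the surface spike at
`d = T` occupies the bin above the shallowest-penetrant bin.  The
statistic is monotone in the penetration fraction `p` only while the
surface spike remains modal (`p ≤ k/(k+1)` for `k = T/b` uniform bins);
beyond that the anchor moves to the flat interior — flagged as a regime
change — and the expectation is no longer monotone.  Measured agreement
between the sampled pipeline at n = 10^6 and the closed form is 0.05–0.65%
across `p ∈ {0, 0.25, 0.5, 0.75, 1}`.

## Generative model (synthetic data)

The generator emulates the chamber geometry with known ground truth; its
defaults are the study conditions used throughout the tests.

- **Tissue surface**: Gaussian-filtered white noise (correlation length
  20 µm), peak-normalized so all heights lie within `mean_z ± amplitude`;
  amplitude 0 gives a flat surface.
- **Bead depths**: mixture — with probability `1 − p` a bead stays at the
  surface (depth 0 plus Gaussian jitter, default 2 µm in the demo
  cohorts), with probability `p` it penetrates to a depth drawn from a
  law truncated to the layer `[0, T]`.  The true depth profile of a
  defective layer is not characterized quantitatively anywhere we know
  of; **uniform** is the default (maximum-entropy choice on the layer)
  and a truncated **exponential** (surface-weighted) is provided so the
  statistic is validated under more than one law.  `d = T − depth`.
- **Rendering**: tissue channel fills voxels below the surface; each bead
  becomes a sphere, where a voxel is lit when the sphere *touches* it
  (center within radius + half voxel diagonal).  This is a deliberate
  stand-in for PSF broadening: a 1-µm bead at typical voxel sizes
  (1–2 µm) would otherwise occupy at most one voxel and be
  indistinguishable from shot noise.  No optical PSF, diffusion, or
  mucin biochemistry is modeled.  Beads outside the volume are listed in
  a clipping report.  When detection counts matter, beads are placed
  with a minimum pairwise separation by rejection sampling so rendered
  blobs cannot merge.
- **Thickness series**: `T(t) = T0 + rate·t` plus Gaussian noise
  (default σ = 10 µm, a realistic micromanipulator repeatability),
  5 locations × {0, 15, 30, 45} min.
- **Cohorts**: per-group Gaussian covariates and mucus parameters.  Demo
  conditions: lean `p = 0.1`, growth 2.0 µm/min; ob/ob `p = 0.6`, growth
  1.0 µm/min; both `T = 80 µm` (bead-scale layer thickness), initial
  explant thickness 400 µm; 8 mice/group, 3 stacks/mouse, 300
  beads/stack; insulin in µU/ml so HOMA-IR uses the standard constant.
  These magnitudes reproduce the qualitative study design — a strong
  penetrability/growth-rate defect in separately housed obese mice —
  without being calibrated to any published curve.  **Co-housing** is
  modeled as convergence of the mucus parameters (penetration fraction,
  layer thickness, growth-rate mean) to the across-group mean, scaled by
  a `convergence` factor (default 1 = full convergence, matching the
  observed abrogation of the barrier differences); metabolic covariates
  remain genotype-specific.

What passing tests on these synthetics do *not* show: robustness to real
optics (PSF, attenuation with depth, channel bleed-through), villus
geometry in small-intestinal stacks, bead aggregation, or non-linear
mucus growth.

## Stack analysis

The tissue isosurface is approximated per (x, y) column by the topmost
voxel at or above a threshold (default 0.5 of the channel maximum);
columns with no supra-threshold voxel are masked invalid.  Beads are
segmented by thresholding (fraction-of-max by default; an absolute
threshold can be supplied, which is the robust choice for fields that may
contain no beads), 26-connected component labeling, a minimum size of 2
voxels to reject single-voxel speckle, and intensity-weighted centroids.
Physical positions are voxel centers: `index·step + step/2`, 0-based,
z increasing apically.  The surface height under a bead is bilinearly
interpolated between valid cell centers (with linear extrapolation within
the half-pixel border); beads over invalid cells are excluded and
counted.  Interpolation (rather than nearest-column lookup) is a choice
of unknown consequence relative to commercial isosurface-rendering
workflows, exact on flat and linear surfaces.

Measured end-to-end on noise-free 256×256 phantoms: all well-separated
beads detected, distance RMS error ≈ 1.1–1.3 µm at a 2-µm z-step.

## Growth-rate fit

Ordinary least squares of thickness on time, pooling all locations (more
stable than per-location fits at 4 time points; a per-location average is
available).  Initial thickness is the mean measured value at t = 0 when
present, otherwise the fitted intercept (flagged).  Perfectly constant
series are handled explicitly (rate 0, r² = 1).  Rates are µm/min.
Measured: zero bias on noise-free series; |bias| < 0.5% and ≈ 94% 2-SE
coverage over 200 noisy series at σ = 10 µm.

## Cohort statistics

- **HOMA-IR** = glucose [mM] × insulin [µU/ml] / 22.5 (the standard
  constant; a ng/ml → µU/ml helper with configurable factor, default
  28.8, covers ELISA readouts in mass units).  Absolute HOMA-IR values
  depend on the insulin units of the source assay; ordering and
  bilinearity do not.
- **Diabetes label** (NOD design): postprandial glucose strictly
  above 14.5 mM.
- **Two-group comparison**: unpaired t test when both groups pass the
  D'Agostino–Pearson omnibus normality test at α = 0.05, two-sided
  Mann–Whitney U otherwise.  The normality test is undefined below
  n = 8; smaller groups (4–10 mice is typical here) route to the
  nonparametric path.  Mann–Whitney p-values are exact (full null
  enumeration) for tie-free data with combined n ≤ 14, tie-corrected
  normal approximation with continuity correction otherwise.
- **Correlation**: Pearson when both variables pass the normality gate,
  Spearman otherwise (exact permutation p for n ≤ 9, t approximation
  above).  A least-squares regression line is attached only when
  p ≤ 0.05, mirroring the convention that a plotted regression line
  marks a significant correlation.  Two-sided tests throughout; no
  multiple-testing correction across panels.

Measured calibration (this package's simulations): type-I error of the
group comparison on null cohorts 4.7–5.3% at nominal 5% (1000
replicates); power 100% at the separated-cohort effect size with
10 mice/group.

## Numerical conventions and degenerate inputs

- Modal-tie tolerance 5% (above); all randomness flows from explicit
  integer seeds through `numpy.random.default_rng`.
- Empty distance sets, all-zero histograms, all-invalid surfaces,
  single-time-point series, zero-variance correlation inputs: explicit
  errors.  All-background tissue channels, zero detected beads,
  degenerate identical-sample tests: valid results with warnings.
- TSV columns carry unit suffixes (`thickness_um`, `time_min`); reruns
  with the same seed produce byte-identical outputs.

## Problem sizes

Validation experiments use 10^6 beads for oracle agreement, 10^4 beads ×
20 seeds × 5 penetration levels for monotonicity, 256×256×~65-voxel
phantoms with 50 beads for image recovery, 200 series for growth-rate
recovery, 1000/100 replicates for type-I/power, and 50 seeds for the
two-cohort study-shape check — sizes at which the Monte-Carlo error is
well below the effects being verified while the whole suite stays
interactive.
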