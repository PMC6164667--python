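# Methods

## Pipeline model

Each ROI is treated as an independent texture sample. The processing chain
is: ROI mask → μ ± 3σ outlier rejection → uniform quantization to Ng levels
→ histogram + GLCM + GLRLM features → cohort screening. All choices below
are the package's normative contract; where a convention had to be fixed to
make results reproducible, the subsection says so and why.

## ROI geometry

ROIs are discs (one slice) or balls around an integer seed voxel. A voxel
belongs to the ROI iff the Euclidean distance between voxel centers is
≤ radius, measured in voxel units on all axes: anisotropic slice thickness
(e.g. 1×1×1.2 mm) is deliberately *not* corrected for, because radii are
specified in pixels and the 2D/3D panels are meant to be comparable on the
raw grid. The inclusive boundary (≤, voxel centers) is the common convention
and is pinned; a tool using strict `<` or corner geometry will produce
slightly different voxel counts (ours: 29 voxels for a radius-3 disc, 123
for a radius-3 ball, verified against lattice-point enumeration). ROIs that
would be clipped by the volume edge are refused rather than truncated —
truncation silently changes every downstream statistic. External binary
NIfTI masks are accepted in place of interactive drawing.

The default slice axis for discs is the grid axis labeled coronal from the
image orientation (axis 1 for RAS-ordered grids).

## Preprocessing

* μ and σ are the mean and **population** standard deviation (divide by n)
  of in-mask intensities; the population form is fixed so tests are
  deterministic — the difference is immaterial at the ROI sizes used.
* Voxels outside [μ−3σ, μ+3σ] are rejected, becoming holes in the ROI; they
  never contribute to any matrix, and no pair or run bridges a hole. For any
  input distribution the rejected fraction is < 1/9 (Chebyshev); for
  Gaussian intensities it is ≈ 0.27%. If the computed σ is exactly 0
  (constant ROI, or variance underflow) the interval test is meaningless and
  all in-mask voxels are kept.
* Quantization: `level = min(floor((x−xmin)·Ng/(xmax−xmin))+1, Ng)` over
  surviving voxels, with Ng = 64 by default (configurable, ≥ 2). A constant
  ROI maps to level 1. The min/max anchoring makes the whole feature panel
  invariant to affine intensity rescaling of the ROI, which stands in for
  scanner gain differences.
* Both steps are per-ROI, not per-volume, so each ROI is normalized against
  its own tissue statistics.

## Texture features

* **Histogram features** are computed on the quantized levels (after
  rejection), not on raw intensities, so that all 25 features share one
  preprocessing chain. This is a contract of this package: a tool computing
  Global Variance on raw intensities will differ by the (squared)
  quantization scale factor.
* **GLCM**: symmetric pair counting (each pair enters as (i,j) and (j,i)) at
  step distance 1, one directional matrix per offset, each normalized to sum
  1 before weighted averaging. Symmetric counting makes the matrix symmetric
  and Correlation well-defined with equal marginals. Directions that contain
  no valid pair (possible in tiny or hole-riddled ROIs) carry no information
  and are dropped, with the remaining weights renormalized so the averaged
  matrix still sums to 1; if no direction has a pair the ROI is degenerate
  and its feature row is missing. Entropy uses log base 2 (bits).
* **GLRLM**: runs are maximal sequences of equal-level valid voxels along a
  direction, broken by grid edge, holes and level changes; directional run
  matrices are averaged with the same weights, so the total run weight Nr is
  real-valued and Run Percentage = Nr/Np uses the valid voxel count Np.
* **Direction sets**: 2D uses the 4 in-plane offsets {(0,1),(1,1),(1,0),
  (1,−1)} with equal weights; 3D uses the 13 antipodal-unique offsets of the
  26-neighborhood with weights ∝ 1/‖d‖₂ (normalizer 3 + 6/√2 + 4/√3),
  compensating the longer lattice step of diagonals. Inverse-length 3D
  weighting is pinned as this package's reading of "averaged differently to
  account for discretization length"; an implementation using equal 3D
  weights is also supported via the `weighting` option but is not the
  default. Because weights depend only on ‖d‖, features are exactly
  invariant under in-plane rotations/flips (2D) and axis permutations (3D);
  the test suite checks this to 1e-9.
* **Kurtosis** is non-excess (normal → 3); subtract 3 for excess kurtosis.
* Degenerate values (Correlation, Skewness, Kurtosis when σ = 0) are
  missing (NaN → "NA" in CSV), never 0 — silent zeros would bias the group
  statistics.

## Group statistics

Per feature and ROI: one-way ANOVA F-test across all groups (raw feature
values, no transformation) and two-sided MWW tests per group pair. MWW is
exact (full enumeration) when the pooled sample has ≤ 12 tie-free
observations, otherwise the normal approximation with tie and continuity
corrections; two identical samples give p = 1. Bonferroni
(`min(1, m·p)`) and Benjamini–Hochberg (step-up) corrections are applied
within a family; the default family is the 25 features of one ROI for one
comparison, because per-ROI significance counts are the reporting unit. The
family rule is configurable (`pooled` merges ROIs) rather than hidden. When
a feature's test is missing (degenerate ROI, too few usable values), m is
the number of tests actually performed in that family. Missing values are
dropped per test, never imputed. Significance flags use strict
`adjusted p < α`, α = 0.05 by default, and satisfy Bonferroni ⇒ BH ⇒ raw
for every entry.

## Phantom generator

A phantom volume is `mean_intensity + gradient·x₀ + noise`, with noise =
Gaussian white noise (sd `noise_sd`) convolved with a Gaussian kernel of
FWHM `smooth_fwhm_vox` voxels. Smoothing injects spatial autocorrelation —
the single texture knob — with a predictable effect direction: GLCM
Correlation rises and Contrast falls with FWHM (checked as a monotonicity
test over FWHM ∈ {0, 1, 2}). The linear gradient adds the kind of smooth
intensity drift real MR images have, exercising the μ ± 3σ step.

Defaults mirror a three-group hippocampus study: groups CN/EMCI/AD with 35
subjects each, two seed centers (left/right) in a 48³ grid with 1×1×1.2 mm
spacing, equal mean (1000) and noise (100) across groups and graded
smoothing FWHM 0.5/1.0/1.5 voxels, so groups differ in texture, not
brightness. The FWHM grading is this package's choice of a "realistic"
effect — strong enough to be detectable at n = 35 but not trivially
separable.

What the phantoms do *not* emulate: anatomy, bias fields, motion or partial
volume effects, inter-scanner variation. Passing phantom tests therefore
demonstrates correctness of the computation and calibration of the
statistics, not clinical sensitivity on real MRI.

Determinism: one `numpy.random.SeedSequence` per cohort, spawned into one
PCG64 stream per subject, so volumes are bit-reproducible for a given seed
on any platform and independent of generation order.

## Test design and problem sizes

* Matrix construction is verified against brute-force pair/run enumerators
  (explicit loops, no shared code) on 50+ random grids ≤ 6³ with Ng ≤ 4,
  exactly.
* Exact MWW is verified against full enumeration of all rank splits for all
  sample-size pairs with n ≤ 10; BH against a literal step-up
  implementation.
* Null calibration uses 200 phantom cohorts of 10 subjects per group with
  identical texture in all groups, one radius-5 spherical ROI each (the
  middle standard radius); the mean BH-flagged fraction must stay within
  α + 2 standard errors. Power uses 50 cohorts of 20 per group with one
  group at FWHM 2 versus 0: Correlation and Contrast must be BH-flagged
  against both null groups in ≥ 90% of cohorts while the null pair stays at
  null rates. These sizes keep the whole suite around a minute on one CPU
  while leaving the Monte-Carlo error well below the tested margins.
* `scripts/acceptance.py` runs the full default-scale cohort (105 subjects ×
  12 ROIs) end to end.

## Known limitations

* Equivalence with any particular MATLAB radiomics implementation is not
  guaranteed: boundary rule, histogram-feature domain and exact 3D weight
  normalization are pinned here but vary across tools.
* Single step distance (1 voxel) for GLCM; no multi-distance analysis, no
  gray-level size-zone matrices, no gradient/LBP/wavelet features.
* No spatial normalization, registration, bias-field correction or
  automatic seed placement; centers are user input.
* The exact/asymptotic MWW switch at pooled n = 12 creates a (documented)
  discontinuity in p-value methodology across sample sizes.
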