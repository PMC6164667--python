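# hippotex

Rotation-invariant texture-feature screening of seeded regions of interest
(ROIs) in volumetric MRI, aimed at studies that compare local image texture —
for example of the hippocampus — across diagnostic groups such as cognitively
normal (CN), early mild cognitive impairment (EMCI) and Alzheimer's disease
(AD) cohorts.

## What it computes

For each subject, circular (single coronal slice) and spherical ROIs are
placed around user-supplied seed voxels at concentric radii (default 3, 5 and
8 voxels: six ROIs per seed, twelve per subject with left/right seeds). Each
ROI is preprocessed by **μ ± 3σ outlier rejection** (voxels outside three
standard deviations of the ROI mean are discarded, not clipped) and **uniform
quantization to Ng = 64 gray levels**, then described by a panel of **25
texture features**:

* **3 histogram features** — Global Variance, Skewness, Kurtosis of the
  quantized level distribution;
* **9 GLCM features** — Energy, Contrast, Entropy, Homogeneity, Correlation,
  Sum Average, Variance, Dissimilarity and Autocorrelation of the gray-level
  co-occurrence matrix `p(i,j)`, e.g.
  `Contrast = Σᵢⱼ (i−j)² p(i,j)` and
  `Correlation = (Σᵢⱼ ij·p(i,j) − μ²)/σ²`;
* **13 GLRLM features** — SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE,
  LRLGE, LRHGE, GLV and RLV of the gray-level run-length matrix `r(i,j)`,
  e.g. `SRE = Σᵢⱼ ρ(i,j)/j²` with `ρ = r/Nr`.

GLCM and GLRLM are made rotation-invariant by averaging directional matrices:
equally over the 4 in-plane directions (0°, 45°, 90°, 135°) for 2D ROIs, and
over the 13 unique directions of the voxel 26-neighborhood with weights
∝ 1/‖d‖ for 3D ROIs, compensating the longer discretization step of diagonal
directions.

Group screening runs a one-way ANOVA F-test over all groups and pairwise
two-sided Mann–Whitney–Wilcoxon tests per feature, with Bonferroni
(family-wise error) and Benjamini–Hochberg (false discovery rate) corrections
applied within each (ROI, comparison) family of 25 tests, at α = 0.05.

A phantom module generates synthetic three-group cohorts (Gaussian-smoothed
white noise; the smoothing FWHM is the texture knob) so the whole pipeline is
testable end to end without clinical data.

## Worked example

```python
import hippotex as hx

vol, center = hx.worked_example()            # 32^3 smoothed-noise phantom
mask = hx.spherical_mask(vol.shape, center, 5.0)
feats = hx.extract_features(vol, mask)       # 25 named features
for k in ("Global Variance", "Energy", "Contrast", "Correlation", "SRE", "RP"):
    print(f"{k:16s} {feats[k]:.4f}")
```

prints

```
Global Variance  137.9902
Energy           0.0008
Contrast         233.6349
Correlation      0.1478
SRE              0.9867
RP               0.9823
```

Global Variance ≈ 138 on 64 levels and Kurtosis ≈ 2.9 describe a broad,
nearly Gaussian level histogram; the low Energy (0.0008) and positive GLCM
Correlation (0.148) reflect the spatial autocorrelation injected by the
phantom's FWHM-1.2 smoothing; SRE and RP near 1 say that almost all runs
have length 1, i.e. the texture is still noise-dominated at 64 levels.

## Command line

```sh
hippotex simulate --spec spec.yaml --out cohort/
hippotex extract  --volumes cohort/ --centers cohort/centers.csv \
                  --groups cohort/groups.csv --radii 3,5,8 --levels 64 \
                  --out features.csv
hippotex evaluate --features features.csv --alpha 0.05 --family per-roi \
                  --out results/
```

`evaluate` writes `results.csv` (per feature × ROI × comparison: raw,
Bonferroni- and BH-adjusted p-values with significance flags) and
`summary.csv` (significant-feature counts per ROI and comparison).

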