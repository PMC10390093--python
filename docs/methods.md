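# Methods

## Problem and model

Gliomas differ in growth pattern by grade: low-grade gliomas (LGG) tend to be
compact and well-circumscribed, while high-grade gliomas (HGG) are larger,
infiltrative and morphologically irregular. `fracmorph` quantifies that
contrast from binary segmentation masks using the box-counting fractal
dimension (FD) of three morphological aspects of each region — the **general
structure** (the mask itself), its **boundary** (one-voxel outline) and its
**skeleton** (one-voxel medial thinning) — across five regions per subject:
whole tumor, enhanced tumor, edema, and non-tumorous gray and white matter
(tissue masks with the tumor subtracted). That yields 15 FD features per
subject. As a texture baseline, five gray-level co-occurrence (GLCM) features
per region — angular second moment (ASM), contrast, inverse difference
moment (IDM), correlation, entropy — give 25 more.

### Box-counting FD

A set covered by a grid of boxes of side `S` obeys `N(S) ∝ S^(−D)` with `D`
the box-counting dimension. We count occupied boxes on a grid anchored at
array index 0 (zero-padded to a multiple of `S`, no offset sweep), over a
geometric schedule `S = 1, b, b², …` capped at half the shortest axis
(base `b = 2` by default, `b = 3` for the carpet fixtures). `D` is the
negated slope of an OLS fit of `log₁₀N` on `log₁₀S`; `r²` is reported so a
poor scaling regime is visible. Conventions: a perfectly flat curve (single
voxel) has `D = 0` with `r² = 1` (the flat line is an exact fit); empty
regions yield missing records rather than errors, because an enhancing
component can be genuinely absent in low-grade disease.

Because the schedule spans the full range up to half the image, estimates of
finite smooth shapes deviate from the asymptotic dimension in known ways: a
smooth closed curve of modest radius reads ≈ 0.85–0.95 (coarse scales
flatten the curve), a full-image square frame reads ≈ 1.05–1.1 (corner boxes
and the coarse tail). Aligned self-similar sets (Sierpinski carpet/triangle,
filled squares, lines, points) are recovered exactly, to ≥ 6 decimals with
`r² = 1`, and that exactness is the estimator's primary validation.

### Morphological aspects

Boundary: a set voxel survives iff it has ≥ 1 unset face-neighbor
(4-connectivity in 2-D, 6 in 3-D; outside the array counts as unset) — i.e.
the mask minus its face-connected interior. Skeleton: iterative
topology-preserving thinning (Zhang–Suen-style in 2-D, medial-axis in 3-D)
plus a 2-D final pass that deletes *simple* pixels (local foreground-8 /
background-4 component counts preserved) inside residual 2×2 blocks.
Limitation: a 2×2 plate whose four corners each anchor a diagonal arm cannot
be thinned by deletion without disconnecting an arm; in that configuration
topology wins and the plate is retained. Such configurations arise in
salt-and-pepper noise, not in segmentation-mask-like regions.

### GLCM texture

Intensities inside each region are min–max rescaled to 8-bit (constant
regions map to 0). Pairs at displacement 1 pixel, 0° (configurable),
counted only when both endpoints lie inside the mask, asymmetric by default,
256 levels. Entropy uses the natural log. Correlation is missing (NaN) for
zero-variance regions. Because the quantization is min–max normalizing,
texture features are invariant to affine intensity rescaling of a region —
only the *structure* of the intensity pattern matters.

### Statistics

Per feature: Student's t-test if both groups pass Shapiro–Wilk at α = 0.05,
otherwise Mann–Whitney U; two-sided. Benjamini–Hochberg FDR is applied
within each feature family separately (15 FD tests; 25 texture tests),
significance at adjusted p < 0.05. Identical zero-variance samples get
p = 1. Calibration is verified empirically: the gated test's type-I error is
0.05 ± 0.01 under Gaussian nulls at the study's group sizes (n = 27 vs 15).

### Classification

SVMs (linear / polynomial / RBF; C = 1, `gamma = "scale"`), features
standardized with training-fold statistics only. Default resampling is five
repeated stratified 70/30 train/test splits (plain stratified 5-fold via
`cv_mode="kfold"`); the two modes exist because "five-fold cross-validation
with a 70/30 split" is self-contradictory as a single scheme, and the
repeated-split reading honors both numbers. The high-grade class is
positive for sensitivity/specificity. AUC comes from decision-function
scores and equals the all-pairs ranking probability (tested against a
brute-force oracle). The best kernel is chosen by AUC with ties broken by
accuracy, then simplicity (linear < poly < rbf).

## Synthetic cohort generator

The study conditions are two groups of segmented subjects, 27 LGG-like vs
15 HGG-like, on 256×256 2-D slices (an optional 3-D pathway exists in the
fractal/morphology operators; the cohort generator is 2-D, matching the
per-slice reading of the FD analysis).

Tumor mask: a radially perturbed disc. The radius profile is
`r(θ) = R·(1 + 0.85·a·p(θ))` where `p` is a normalized sum of
`roughness_frequency` random-phase sinusoids and `a ∈ [0, 1]` is the
roughness amplitude; branches are thick random walks grown outward from
boundary points; the final mask is the connected component containing the
core. Enhanced tumor is a smaller, equally rough blob intersected with the
whole tumor; edema is the outer ring of the whole tumor (whole minus an
eroded core). GM/WM are nested wobbled ellipses (cortical ribbon + deep
core) with the tumor subtracted, so the non-tumorous invariants hold by
construction.

Group distributions (defaults, chosen once as the study conditions):

| parameter | LGG-like | HGG-like | meaning |
|---|---|---|---|
| base radius (px) | 30 ± 4 | 48 ± 5 | tumor size on the slice |
| roughness amplitude | 0.08 ± 0.04 | 0.55 ± 0.10 | relative boundary perturbation |
| harmonics | 6 | 16 | boundary wiggle frequency content |
| branches (Poisson mean) | 0.3 | 6 | infiltrative protrusions |
| branch length (px) | 12 | 30 | protrusion extent |
| enhanced-region contrast level | 0.5 | 4.0 | texture heterogeneity of the core |

These encode the clinically described contrast — high-grade tumors are
larger, rougher and more heterogeneously enhancing — and make the
enhanced-region general-structure FD the planted discriminator the analysis
is designed to detect. With 256² slices and the full base-2 schedule, the
mean enhanced-region general FD lands near 1.24 (LGG-like) vs 1.44
(HGG-like): higher in the high-grade group, as expected for more
space-filling, irregular masks at fixed resolution. A `null_effect()`
preset draws both groups from the LGG distribution for calibration runs.

Texture interiors: intensity = 128 + amplitude·(smoothed Gaussian noise
field) + pixel noise, supported on the mask. `contrast_level` scales the
amplitude *and* sharpens the field's spatial scale
(`σ = max(0.5, 3/(1+level))`); the second effect is what survives min–max
quantization, so GLCM contrast/entropy increase monotonically with the
level, and level 0 with zero noise gives an exactly constant region.

Randomness: one master seed; subject *i* uses
`SeedSequence(entropy=seed, spawn_key=(i,))`, so any subject is reproducible
in isolation and cohorts are identical across runs.

### What the generator does and does not emulate

It emulates the *shape statistics* the FD analysis claims to detect
(circumscribed vs irregular), region nesting/disjointness, cohort
imbalance, and group-dependent texture heterogeneity. It does not emulate
MRI physics (no bias field, partial voluming, acquisition noise spectra),
real anatomical geometry, registration error, or inter-rater segmentation
variability. Passing tests therefore demonstrate that the *pipeline*
measures what it claims on masks with known properties — not that FD
separates clinical LGG from HGG; that claim belongs to studies with real
cohorts.

## Numerical choices and problem sizes

- Replicate experiments use the full study conditions (27/15 subjects,
  256² canvas): 100 replicates for effect recovery, 50 for null
  calibration in the test suite; the standalone results script uses 20 and
  15 replicates with seed-derived substreams.
- Box-count container enforces nonincreasing counts, which holds exactly
  for the nested (divisibility-chain) schedules the scheduler produces.
- Degenerate inputs: empty masks are rejected by analysis entry points
  (I/O accepts them with a warning); 1-pixel regions yield missing texture
  records (no co-occurring pairs); constant samples route to the
  Mann–Whitney branch; degenerate CV folds are skipped with the fold count
  reported.

## Known limitations

- FD estimates are resolution- and schedule-dependent for non-fractal
  finite shapes; compare groups only at a fixed canvas and schedule.
- Single grid origin (no offset minimization): estimates on sparse sets can
  shift by a few hundredths under translation.
- The texture defaults (offset (0,1), asymmetric, 256 levels) are one
  convention among several; all are configurable.
- 3-D cohort simulation is not implemented (the operators accept 3-D
  arrays; the generator produces 2-D slices).
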