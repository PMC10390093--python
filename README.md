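# fracmorph

Fractal and texture analysis of brain-tumor segmentation masks.

`fracmorph` implements a complete pipeline for discriminating low-grade from
high-grade glioma-like morphology using the **box-counting fractal
dimension** (FD) of segmented regions, backed by gray-level co-occurrence
(GLCM) texture features, gated group statistics with FDR correction, and
cross-validated SVM classification. Because real imaging data cannot ship
with the package, it includes a synthetic cohort generator that produces
segmentation masks with the shape statistics the method claims to detect —
compact, smooth tumors in one group; larger, rougher, more infiltrative
tumors in the other — so every claim is testable end to end.

## The scientific problem

Tumor grade correlates with growth pattern: low-grade gliomas (LGG) are
typically circumscribed, high-grade gliomas (HGG) infiltrative and
irregular. The box-counting dimension quantifies that irregularity. Cover a
set with a grid of boxes of side `S` and count occupied boxes `N(S)`; for a
(statistically) self-similar set `N(S) ∝ S^(−D)`, and `D` — the negated
slope of `log N` against `log S` — measures how completely the set fills
space. A smooth outline has `D ≈ 1`; a convoluted, space-filling one pushes
toward 2.

Each subject contributes five regions (whole tumor, enhanced tumor, edema,
non-tumorous gray matter, non-tumorous white matter) and each region three
morphological aspects (the general structure, its boundary, its skeleton):
15 FD features, plus 25 GLCM texture features (ASM, contrast, IDM,
correlation, entropy per region). Groups are compared per feature with a
normality-gated t-test / Mann-Whitney U and Benjamini–Hochberg FDR; single
features and per-region feature groups are ranked by cross-validated SVM
AUC. See [docs/methods.md](docs/methods.md) for the full model, parameter
rationale and limitations.

## Worked example

Exact recovery on a reference fractal, then FD of a simulated high-grade
subject:

```python
from fracmorph.synthetic import ShapeSpec, gen_reference_fractal, gen_cohort
from fracmorph.fractal import estimate_fd, fd_of_aspects
from fracmorph.structure import extract_all_aspects
from fracmorph.texture import region_texture

carpet = gen_reference_fractal(ShapeSpec(kind="sierpinski_carpet", depth_or_size=5))
res = estimate_fd(carpet, base=3)
print(f"carpet: D = {res.D:.6f}, r^2 = {res.r_squared:.6f}")

cohort = gen_cohort(n_lgg=2, n_hgg=2, seed=7)
subj = next(s for s in cohort.subjects if s.label == "HGG")
aspects = extract_all_aspects(subj.masks["enhanced_tumor"])
for rec in fd_of_aspects(aspects, region="enhanced_tumor"):
    print(f"{rec.region} {rec.aspect}: D = {rec.D:.3f} (r^2 = {rec.r_squared:.3f})")
feats = region_texture(subj.images["enhanced_tumor"], subj.masks["enhanced_tumor"])
print(f"GLCM contrast = {feats.contrast:.1f}, entropy = {feats.entropy:.2f}")
```

Output:

```
carpet: D = 1.892789, r^2 = 1.000000
enhanced_tumor general: D = 1.489 (r^2 = 0.976)
enhanced_tumor boundary: D = 1.098 (r^2 = 0.982)
enhanced_tumor skeleton: D = 1.060 (r^2 = 0.981)
GLCM contrast = 1359.8, entropy = 7.75
```

The analytic carpet dimension is `log 8 / log 3 = 1.8927892607…`; the
estimate matches to machine precision.

## The full analysis

The study lives in numbered drivers under `analysis/` (run from the
repository root; each writes to `results/`):

```bash
python analysis/01_reference_fractals.py   # validate the FD estimator
python analysis/02_simulate_cohort.py      # simulate the 27-vs-15 cohort
python analysis/03_extract_features.py     # 40 features x 42 subjects
python analysis/04_group_stats.py          # gated tests + FDR per family
python analysis/05_classify.py             # SVM ranking of feature sets
```

Headline numbers from this sequence (master seed 7):

- **Estimator validation** — all five reference shapes recovered with
  absolute error ≤ 4.5 × 10⁻¹⁶ (carpet 1.892789, triangle 1.584963,
  square 2, line 1, point 0; `results/reference_fd.csv`).
- **Group contrast** — enhanced-region general-structure FD: LGG-like
  1.235 vs HGG-like 1.437; whole-tumor boundary FD: 0.867 vs 1.127
  (t-test, adjusted p = 3.3 × 10⁻²¹).
- **Statistics** — 13/15 FD and 14/25 texture features significant after
  within-family FDR; every significant FD feature runs higher in the
  high-grade-like group.
- **Classification** — several single FD features reach AUC 100% under the
  planted effect; e.g. whole-tumor skeleton FD classifies at 100%
  accuracy / 100% AUC and whole-tumor boundary FD at 98.5% / 100%
  (`results/classification.csv`).

## Layout

```
src/fracmorph/      the package: synthetic, image_io, structure, fractal,
                    texture, group_stats, classification, pipeline, cli
analysis/           numbered study drivers (the experiment itself)
scripts/            acceptance.py (end-to-end recomputation)
tests/              pytest suite with brute-force oracles
docs/methods.md     methods note: model, parameters, numerics, limitations
```
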