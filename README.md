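# rainbowspec

A low-cost food-authentication toolkit built around diffraction-grating
("rainbow") photography. It turns a photograph of a dispersed-light patch
on a dark background into a 100-point pseudo-spectrum and classifies
samples (e.g. organic vs non-organic fruit) with five chemometric
algorithms under a deterministic evaluation protocol.

The pipeline:

1. **segmentation** — grayscale conversion, median-filter denoising,
   Otsu thresholding (between-class-variance maximization), an HSV
   saturation gate, morphological clean-up and largest-component
   selection; the RGB crop is resampled to a standard 100×100 patch with
   the dispersion axis along the rows.
2. **features** — per-pixel weighted channel combination
   `F = 0.2·R + 0.7·G + 0.1·B` followed by row averaging, yielding one
   length-100 feature vector per image; matrices serialize to CSV.
3. **preprocess** — Savitzky–Golay smoothing (degree 2, 33-point window)
   by default; SNV, min-max, area normalization and polynomial baseline
   correction as alternatives. All transforms are per-row, so there is no
   train/test leakage by construction.
4. **classifiers** — k-NN, a PUK-kernel SVM, PLS-DA (NIPALS), kernel
   PLS-DA (Gaussian kernel, dual form) and a locally weighted PLS
   classifier (LW-PLSC) that fits a per-query, distance-weighted PLS-DA
   model with similarity weights `exp(−d/(φ·sd(d)))`.
5. **evaluation** — deterministic DUPLEX 2:1 train/test splitting,
   leave-one-out cross-validated grid search
   (k ∈ {1,3,…,49}; LVs ≤ 10; C ∈ 1…8; σ ∈ 10⁻³…10³ log-spaced;
   φ ∈ 0.1…25) with a parsimony tie-break, and overall/per-class
   accuracy reports with confusion matrices.
6. **synthetic_data** — fully seeded generators for (a) rainbow scenes
   with pixel-level ground truth and (b) feature populations with three
   linearly separable species groups and a ring-structured (nonlinearly
   separable) organic/non-organic labelling, certified at generation time
   by a linear-classifier ceiling.

## CLI

```bash
# synthetic fixtures
rainbowspec simulate images --n 10 --seed 0 --noise-sd 3 --out scenes/
rainbowspec simulate features --seed 42 --out population.csv

# photographs -> feature CSV (labels.csv: sample_id,species,type)
rainbowspec extract --images scenes/ --labels scenes/labels.csv --out features.csv

# full protocol: preprocess -> DUPLEX 2:1 -> LOOCV grids -> test report
rainbowspec evaluate --features population.csv --out results/
rainbowspec report --results results/

# fit and serialize a PLS-family model
rainbowspec train --features population.csv --algorithm kplsda --n-lv 5 --sigma 100 --out model.json
```

`evaluate` writes `report.json` / `report.txt` (overall, per-class and
validation accuracy plus selected parameters per algorithm), one
`surface_<algorithm>.csv` accuracy surface per grid search, and a
`manifest.json` with a config hash and library versions for exact
reproduction.

## Notes

- The LW-PLS similarity weight and the PUK kernel parameters are
  interpretations (the standard just-in-time weight from the LW-PLS
  literature, and Pearson VII with ω = 1, σ = 1); both are configurable.
- Model JSON round trips are bit-identical for the PLS family and within
  1e-12 for the kernel family.
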