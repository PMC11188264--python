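# sersraman

Combined SERS–Raman analysis of single breast-epithelial cells: simulate,
preprocess, classify and quantify.

Label-free Raman micro-spectroscopy fingerprints the metabolic state of a
cell (aromatic amino-acid bands such as phenylalanine at 1003 cm⁻¹ versus
phospholipid/lipid bands at 1085, 1453, 1660 and 2850–2950 cm⁻¹), while SERS
imaging with antibody-functionalized gold nanoprobes carrying a 4-MBA Raman
reporter (signature bands at 1080 and 1580 cm⁻¹) maps a membrane biomarker
such as HER2 pixel by pixel. This package implements the complete
computational pipeline behind that combined experiment, plus a synthetic-data
generator with known ground truth so every stage is testable without any
measured spectra:

- **synthetic** — forward models for single-cell Raman spectra
  (Lorentzian/Gaussian bands from a literature band dictionary,
  autofluorescence + water background, per-cell amplitude variability,
  shot-like noise) and for SERS hyperspectral maps (elliptical cell
  footprint, discrete nanoprobe occupancy proportional to marker density).
- **preprocess** — crop to 800–3100 cm⁻¹, rubber-band baseline (smoothing
  spline through the lower-convex-hull support points), asymmetric
  least-squares (Whittaker) residual baseline minimizing
  Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)², optional 6 cm⁻¹ rebinning, vector normalization.
- **chemometrics** — PCA via SVD (loadings / scores / explained variances),
  Wilcoxon rank-sum tests on component scores with Holm adjustment,
  cell-grouped 50/50 LDA classification (PCA-reduced Fisher discriminants),
  and the mean misclassification error over repeated random equal-class test
  draws of one tenth of the data.
- **sersquant** — per-map noise threshold **T = mₚ + 3σₚ** from the
  signal-free 890–910 cm⁻¹ window, dual-band bright-pixel counting (a pixel
  counts only if it exceeds T at *both* reporter bands), relative expression
  between conditions, and the substrate enhancement factor
  EF = (I_SERS/N_SERS)/(I_ref/N_ref).
- **io / cli** — wide-CSV spectra, long-CSV hyperspectral maps, YAML
  configuration, deterministic JSON reports; a `sersraman` command with
  `simulate-raman`, `simulate-sers`, `preprocess`, `classify`, `sers-quant`
  and `report` subcommands.

The high-level interface follows the model/results convention:
`RamanCellClassifier(data).fit(seed=...)` and
`SersQuantifier(conditions, reference=...).fit()` return results objects
with estimates, diagnostics and a `summary()` table.

## Worked example

```python
from sersraman import RamanCellClassifier, SersQuantifier
from sersraman.synthetic import (
    make_default_profiles, simulate_raman_dataset, simulate_sers_condition)

# Raman arm: 3 classes x 30 cells x 9 spectra
data = simulate_raman_dataset(make_default_profiles(), n_cells=30,
                              spectra_per_cell=9, rng_seed=1)
res = RamanCellClassifier(data).fit(n_iterations=200, seed=1)
print(res.summary())
```

prints (abridged):

```
Raman cell-line classification
==============================================
spectra (train/test)       405 / 405
classes                  her2_high, normal, triple_negative
PC1-4 cumulative var.     91.14 %
held-out LDA accuracy    100.00 %
mean misclassification    0.000 % (200 iterations, 27 test spectra/class)
```

The first four principal components carry 91% of the total spectral
variance; the LDA trained on half of the cells classifies every held-out
spectrum correctly, and the repeated-draw misclassification error is 0%.
Wilcoxon tests on each PC's scores flag all pairwise class contrasts at
`****` (p < 0.0001).

```python
# SERS arm: marker-silenced condition at 7% of the reference density
conditions = {
    "scrambled": simulate_sers_condition(30, 0.4, rng_seed=1),
    "silenced": simulate_sers_condition(30, 0.028, rng_seed=2),
}
print(SersQuantifier(conditions, reference="scrambled").fit().summary())
```

```
SERS bright-pixel quantification
========================================================
condition            maps  total px  mean/cell    rel %
scrambled              30      3209      107.0    100.0
silenced               30       224        7.5      7.0
reference condition: scrambled
silenced: 7.0 % of reference (93.0 % reduction)
```

The dual-band bright-pixel count recovers the ground-truth 7% marker density
ratio — a 93% reduction, the regime of an efficient gene silencing — from the
thresholded maps alone.

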