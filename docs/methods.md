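# Methods

## Overview

The package models a two-arm single-cell experiment on breast epithelial
cell lines. The Raman arm acquires many spontaneous-Raman spectra per cell
from the cytoplasm, removes broad backgrounds, and classifies cells by their
macromolecular fingerprint. The SERS arm maps each cell with
antibody-functionalized gold nanoprobes carrying a 4-MBA reporter and counts
the map pixels in which the reporter's two aromatic-ring bands (1080 and
1580 cm⁻¹) rise above a noise threshold; the bright-pixel count is the
per-cell readout of membrane-marker abundance, and expression is reported
relative to a reference condition.

Because no public raw spectra exist for this kind of experiment, the
synthetic module is a first-class component: it generates both data types
from explicit forward models with stored ground truth, which is what all
property and end-to-end tests measure against.

## Raman forward model

A spectrum on the axis ν (default 600–3400 cm⁻¹ at 2 cm⁻¹) is

    y(ν) = s · Σ_b L_b(ν) + A_f · exp(−(ν − ν₀)/τ) + W(ν) + ε(ν)

where `L_b` are band line shapes (Lorentzian by default — the physical
spontaneous-Raman line shape — Gaussian available per band), `A_f, τ` set an
exponentially decaying autofluorescence (defaults 0.4–0.6 a.u. and
1200 cm⁻¹), `W` is a broad Gaussian water band centred at 3200 cm⁻¹
(FWHM 450 cm⁻¹, amplitude 0.25 a.u.) whose tail reaches into the cropped
range, and ε is i.i.d. Gaussian channel noise. The per-cell scale `s` is
drawn once per cell from a mean-one lognormal with coefficient of variation
0.10 and shared by all of that cell's spectra: multiplicative, so
intensities stay positive, and removed almost entirely by the final vector
normalization, as overall-brightness differences should be.

Every default band center sits inside an interval of a literature band
dictionary for breast epithelial cells (`RAMAN_BAND_TABLE`); a validator
flags any profile band that does not. The printed source interval
"1155–1557" is treated as a typo for 1155–1157 (its neighbours are 1125–1126
and 1174–1176). The three default classes differ only in per-band
amplitudes, encoding the canonical contrast pattern: aromatic amino-acid
bands (877, 1003, 1033, 1610 cm⁻¹) ranked triple-negative > HER2-high >
normal; phospholipid/lipid/protein bands (1085, 1450, 1660, 2850–2950 cm⁻¹)
ranked HER2-high > triple-negative > normal; the normal class lowest
overall.

Calibration of the free noise level: the acquisition conditions the study
emulates (60 s integration per spectrum) give peak signal-to-noise of order
10²; the default channel noise is 0.005 a.u. against band amplitudes of
0.1–1.0 a.u. This level was fixed once so that the study-scale dataset
reproduces the intended emergent behaviour (first four PCs just above 90% of
total variance, perfect held-out classification) and is exposed in the
profile/background configuration.

## SERS forward model

A map is an nx × ny grid (default 30 × 30 at 1 µm step, spectra 600–1700 cm⁻¹
at 2 cm⁻¹) with an elliptical cell footprint. Marker density per pixel is a
random occupancy field, zero outside the cell:

- `bernoulli` (default): each in-cell pixel holds a bound nanoprobe cluster
  with probability equal to `density_scale`. This is the dilute limit of
  discrete binding events and makes the expected bright-pixel count exactly
  proportional to marker density — the property that lets a count ratio
  estimate an expression ratio without saturation bias. Default reference
  occupancy 0.4, so a 30-cell condition yields count statistics (~3 × 10³
  bright pixels) that determine relative expression to about one percentage
  point.
- `poisson`: Poisson-distributed cluster counts per pixel (occupancy
  saturates as 1 − e^(−λ); retained for studying that regime).
- `uniform`: constant density, used by the linear-response checks.
- `rim`: occupancy concentrated towards the footprint boundary, mimicking
  membrane-localized staining.

Each occupied pixel carries the reporter doublet with peak amplitude
`gain × density` (optional saturation ceiling) on top of i.i.d. Gaussian
noise (default sd 0.02 a.u., single-cluster amplitude 1.0 — a SERS-bright
cluster is far above the noise floor, which is what plasmonic enhancement
of ~10⁶ provides).

## Preprocessing chain

Stage order is fixed: crop → rubber-band subtract → ALS subtract →
(optional rebin) → vector normalize. Cropping to 800–3100 cm⁻¹ discards the
quartz/CaF₂ edge and most of the water band; no dedicated water-subtraction
stage exists — the crop plus the rubber band are taken as the whole of the
water handling.

**Rubber band.** Support points are the vertices of the lower convex hull of
(ν, y), found by a monotone chain; the baseline is a cubic interpolating
spline through them (smoothing parameter zero; linear interpolation when
fewer than four vertices exist, e.g. a straight-line spectrum). The baseline
equals the spectrum at every support point by construction.

**ALS (Whittaker) baseline.** z minimizes Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)² with
wᵢ = p where yᵢ > zᵢ and 1−p elsewhere, starting from uniform weights.
Defaults λ = 10⁵, p = 0.001, at most 10 weight iterations, tolerance 10⁻⁶ —
standard values for Raman-scale axes at ~2 cm⁻¹ spacing (λ^(1/4) ≈ 18
channels ≈ 36 cm⁻¹ smoothing length, below band-envelope scales). Each inner
solve uses the exact symmetric pentadiagonal (Cholesky-banded) system, so
the solution at the current weights is the exact minimizer; convergence is
declared when either the weights or the baseline stabilize (the weight rule
alone can flip forever on floating-point ties). Running out of iterations
sets a flag and logs — it is not an error; on noisy spectra the weight set
often keeps exchanging a few channels without visibly moving the baseline.

**Rebinning.** Contiguous half-open bins [lo, lo + w) anchored at the crop
origin, value = mean of member channels, reported at bin centers. Applied
only on the discriminant-analysis branch (6 cm⁻¹); PCA runs at native
resolution.

**Normalization** to unit Euclidean norm over the full cropped range (the
CH region is not normalized separately).

## Chemometrics

PCA is computed by SVD of the mean-centred matrix; explained-variance
fractions come from the squared singular values, and each loading's sign is
fixed so its largest-magnitude element is positive (deterministic plots).
Score distributions are compared per class pair with the two-sided Wilcoxon
rank-sum test: exact null when the pooled sample is ≤ 20 and tie-free,
otherwise the normal approximation with tie correction and no continuity
correction (so identical groups give p = 1 exactly); Holm-adjusted p-values
are reported beside the raw ones, with the conventional star coding
(`****` ⇔ p < 0.0001).

The LDA operates on the 6 cm⁻¹ branch. Channels far outnumber spectra, so
the within-class scatter is first conditioned by projecting onto the
leading principal components — at most `n_train − n_classes` of them, or
fewer if 99% of variance is reached earlier — and Fisher discriminants are
computed in that space (scikit-learn's SVD solver, which handles any
residual rank deficiency by pseudo-inverse; no explicit ridge is needed
after the reduction). Splits are *cell-grouped*: all spectra of a cell stay
on one side, per-class cell counts balanced to the split fraction within
one cell.

Model stability is summarized as the mean misclassification error over
repeated random test draws: each iteration removes a test subset of one
tenth of the data with exactly equal per-class spectrum counts (whole cells
only, which requires a uniform spectra-per-cell count), trains on the rest
and records the error. The phrase "ten-fold random test set" is read as
independent random tenth-sized draws, not a single 10-fold partition —
equal class size per draw is only well-defined per random draw; 1000
iterations by default, 200 in the test suite and acceptance script (the
estimate is a mean of per-iteration fractions, so the reduced count changes
only its Monte-Carlo error).

## SERS quantification

Per map, the noise statistic pools the per-pixel intensity maxima over the
signal-free 890–910 cm⁻¹ window across *all* pixels; mₚ and σₚ are their
mean and population (1/N) standard deviation — N is ~10³ per map, so the
1/N form is immaterial but documented — and T = mₚ + 3σₚ. One threshold per
map is applied to both reporter bands by default (one noise window defines
one statistic); per-band windows are available by argument. Band intensity
is the window maximum over center ± 10 cm⁻¹ (not a fitted peak height). A
pixel is bright iff it *strictly* exceeds T at both bands — values exactly
at T are excluded. Condition totals sum per-map counts with per-map
thresholds; both raw counts and area-normalized (per-pixel-of-footprint)
counts are reported, since either convention is defensible. Relative
expression is the ratio of total counts × 100, reported alongside the
complementary reduction percentage. The enhancement-factor helper
implements the standard substrate form EF = (I_SERS/N_SERS)/(I_ref/N_ref).

## Reproducibility

All stochastic stages take either an integer seed or a numpy Generator; one
root seed derives child seeds for data generation, splitting and repeated
draws, and identical seeds give bit-identical datasets, maps and results.
The preprocessing chain is fully deterministic. Reports are JSON with
sorted keys, a schema version and the SHA-256 of the configuration that
produced them; CSV floats are written with 17 significant digits and parsed
in round-trip mode, so disk round-trips are bit-exact.

## Problem sizes

The study scale mirrors the emulated design: 3 classes × 30 cells × 9
spectra (810 spectra, 1151 channels after cropping, 384 after rebinning)
for the Raman arm; 30 maps of 30 × 30 pixels per condition for the SERS
arm. The misclassification estimator runs 200 iterations in the suite and
acceptance script; ratio-recovery checks use three generator seeds per
density ratio.

## What the synthetic data does and does not show

Passing tests demonstrate that the pipeline recovers what the forward
models put in: band contrasts survive baseline removal and normalization,
class structure is linearly separable at realistic noise, and bright-pixel
counts track marker density. Real spectra add effects the generator omits
by design: cosmic-ray spikes, detector etaloning, wavenumber-calibration
drift, focus- and depth-dependent background shapes, cell-morphology
variation, nanoparticle aggregation, and biological within-class
heterogeneity far richer than a single per-cell scale factor. Results on
synthetic data therefore validate the *computations*, not instrument- or
biology-level robustness.

## Known limitations

- With heavily overlapping Lorentzian bands, the tail pileup forms a
  pedestal that the rubber band partially treats as background; baselines
  are recovered to correlation ≥ 0.99 for fast-decaying (Gaussian) bands,
  while Lorentzian-tail absorption adds a few percent of systematic band
  distortion. This is inherent to hull-anchored baselines, not an
  implementation artifact.
- The bright-pixel statistic is a counting measure: its precision is set by
  the number of occupied pixels, and in the Poisson (multi-cluster) regime
  the count saturates with density; quantitative ratios assume the dilute
  occupancy regime.
- The EF helper implements the standard substrate formula; it performs no
  molecule-count estimation itself.
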