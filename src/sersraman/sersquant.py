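"""Dual-band noise-threshold quantification of SERS reporter signal.

A pixel of a hyperspectral SERS map counts as "bright" when its band
intensities at both reporter Raman shifts (1080 and 1580 cm^-1 for a
4-MBA-type reporter) strictly exceed the map's noise threshold
``T = mp + 3 * sigma_p``, where ``mp`` and ``sigma_p`` are the mean and the
(population) standard deviation of the per-pixel intensity maxima in a
signal-free spectral window (890-910 cm^-1 by default).  The bright-pixel
count per condition is the quantification statistic; expression relative to a
reference condition is the ratio of total counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import HyperspectralMap

__all__ = [
    "IntensityMap",
    "NoiseThreshold",
    "QuantResult",
    "RelativeExpression",
    "EnhancementInputs",
    "band_intensity_map",
    "noise_threshold",
    "bright_pixel_mask",
    "quantify_condition",
    "relative_expression",
    "enhancement_factor",
]

DEFAULT_REPORTER_CENTERS = (1080.0, 1580.0)
DEFAULT_REPORTER_HALFWIDTH = 10.0
DEFAULT_NOISE_WINDOW = (890.0, 910.0)


@dataclass(frozen=True)
class IntensityMap:
    """Per-pixel intensity of one reporter band (window maximum)."""

    values: np.ndarray              # (ny, nx)
    step_um: float
    band_center: float
    band_halfwidth: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or not np.all(np.isfinite(v)):
            raise ValueError("intensity map must be a finite 2-D array")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class NoiseThreshold:
    """T = mp + 3*sigma_p from the signal-free window maxima of one map."""

    mp: float
    sigma_p: float
    noise_window: tuple[float, float] = DEFAULT_NOISE_WINDOW

    def __post_init__(self) -> None:
        if self.sigma_p < 0:
            raise ValueError("sigma_p must be >= 0")

    @property
    def T(self) -> float:
        return self.mp + 3.0 * self.sigma_p


@dataclass(frozen=True)
class QuantResult:
    """Bright-pixel quantification for one or more maps of a condition."""

    bright_masks: tuple[np.ndarray, ...]
    per_map_counts: tuple[int, ...]
    thresholds: tuple[NoiseThreshold, ...]
    cell_areas_px: tuple[int, ...] | None = None

    @property
    def total_count(self) -> int:
        return int(sum(self.per_map_counts))

    @property
    def n_maps(self) -> int:
        return len(self.per_map_counts)

    @property
    def mean_count(self) -> float:
        return float(np.mean(self.per_map_counts))

    @property
    def count_sd(self) -> float:
        return float(np.std(self.per_map_counts))

    @property
    def area_normalized_counts(self) -> np.ndarray | None:
        """Per-map bright fraction of the cell footprint, when masks exist."""
        if self.cell_areas_px is None:
            return None
        return (np.asarray(self.per_map_counts, float)
                / np.asarray(self.cell_areas_px, float))


@dataclass(frozen=True)
class RelativeExpression:
    percent: float
    reduction_percent: float


@dataclass(frozen=True)
class EnhancementInputs:
    """Intensities and molecule counts for the substrate enhancement factor."""

    I_sers: float
    I_ref: float
    N_sers: float
    N_ref: float

    def __post_init__(self) -> None:
        if min(self.I_sers, self.I_ref, self.N_sers, self.N_ref) <= 0:
            raise ValueError("all enhancement-factor inputs must be > 0")


# ---------------------------------------------------------------------------
# Per-band intensity and noise statistics
# ---------------------------------------------------------------------------

def _window_max(hmap: HyperspectralMap, lo: float, hi: float) -> np.ndarray:
    mask = hmap.axis.window_mask(lo, hi)
    return hmap.cube[:, :, mask].max(axis=2)


def band_intensity_map(hmap: HyperspectralMap, center: float,
                       halfwidth: float = DEFAULT_REPORTER_HALFWIDTH) -> IntensityMap:
    """Per-pixel maximum intensity within ``center +- halfwidth``."""
    lo, hi = center - halfwidth, center + halfwidth
    if lo < hmap.axis.lo or hi > hmap.axis.hi:
        raise ValueError(f"band window [{lo}, {hi}] extends outside the map "
                         f"axis [{hmap.axis.lo}, {hmap.axis.hi}]")
    return IntensityMap(values=_window_max(hmap, lo, hi), step_um=hmap.step_um,
                        band_center=center, band_halfwidth=halfwidth)


def noise_threshold(hmap: HyperspectralMap,
                    lo: float = DEFAULT_NOISE_WINDOW[0],
                    hi: float = DEFAULT_NOISE_WINDOW[1]) -> NoiseThreshold:
    """Noise statistic of one map from its signal-free window.

    The per-pixel maximum over [lo, hi] is collected across all pixels of the
    map; ``mp`` and ``sigma_p`` are the mean and population (1/N) standard
    deviation of those maxima.
    """
    if hmap.n_pixels < 2:
        raise ValueError("noise threshold needs at least 2 pixels")
    maxima = _window_max(hmap, lo, hi).ravel()
    return NoiseThreshold(mp=float(maxima.mean()),
                          sigma_p=float(maxima.std()),  # population form
                          noise_window=(lo, hi))


def bright_pixel_mask(i_low: IntensityMap, i_high: IntensityMap,
                      thresholds: NoiseThreshold | tuple[NoiseThreshold, NoiseThreshold],
                      ) -> np.ndarray:
    """Pixels whose intensity strictly exceeds the threshold at BOTH bands.

    A single ``NoiseThreshold`` is applied to both band maps (one noise
    window defines one statistic per map); a pair applies per-band
    thresholds.  Values exactly at T are not bright (strict inequality).
    """
    if i_low.values.shape != i_high.values.shape:
        raise ValueError("band intensity maps have mismatching shapes")
    if isinstance(thresholds, NoiseThreshold):
        t_low = t_high = thresholds.T
    else:
        t_low, t_high = (t.T for t in thresholds)
    return (i_low.values > t_low) & (i_high.values > t_high)


# ---------------------------------------------------------------------------
# Condition-level quantification
# ---------------------------------------------------------------------------

def quantify_map(hmap: HyperspectralMap,
                 reporter_centers: Sequence[float] = DEFAULT_REPORTER_CENTERS,
                 reporter_halfwidth: float = DEFAULT_REPORTER_HALFWIDTH,
                 noise_window: tuple[float, float] = DEFAULT_NOISE_WINDOW,
                 ) -> tuple[np.ndarray, NoiseThreshold]:
    """Bright mask and noise threshold of a single map."""
    thr = noise_threshold(hmap, *noise_window)
    c1, c2 = reporter_centers
    mask = bright_pixel_mask(band_intensity_map(hmap, c1, reporter_halfwidth),
                             band_intensity_map(hmap, c2, reporter_halfwidth),
                             thr)
    return mask, thr


def quantify_condition(maps: Sequence[HyperspectralMap],
                       reporter_centers: Sequence[float] = DEFAULT_REPORTER_CENTERS,
                       reporter_halfwidth: float = DEFAULT_REPORTER_HALFWIDTH,
                       noise_window: tuple[float, float] = DEFAULT_NOISE_WINDOW,
                       ) -> QuantResult:
    """Bright-pixel counts for all maps of one condition.

    The noise threshold is computed independently for each map; the
    condition-level statistic is the summed bright-pixel count.
    """
    if len(maps) == 0:
        raise ValueError("need at least one map")
    masks, counts, thrs, areas = [], [], [], []
    have_cell_masks = all(m.cell_mask is not None for m in maps)
    for hmap in maps:
        bright, thr = quantify_map(hmap, reporter_centers,
                                   reporter_halfwidth, noise_window)
        masks.append(bright)
        counts.append(int(bright.sum()))
        thrs.append(thr)
        if have_cell_masks:
            areas.append(int(hmap.cell_mask.sum()))
    return QuantResult(bright_masks=tuple(masks), per_map_counts=tuple(counts),
                       thresholds=tuple(thrs),
                       cell_areas_px=tuple(areas) if have_cell_masks else None)


def relative_expression(test: QuantResult, reference: QuantResult) -> RelativeExpression:
    """Expression of a test condition as a percentage of the reference.

    Returns both 100 * test/reference and the complementary reduction
    percentage (as used to express biomarker loss after gene silencing).
    """
    if reference.total_count <= 0:
        raise ValueError("reference condition has zero bright pixels")
    ratio = 100.0 * test.total_count / reference.total_count
    return RelativeExpression(percent=ratio, reduction_percent=100.0 - ratio)


def enhancement_factor(inp: EnhancementInputs) -> float:
    """Standard substrate enhancement factor
    ``EF = (I_sers / N_sers) / (I_ref / N_ref)``."""
    return (inp.I_sers / inp.N_sers) / (inp.I_ref / inp.N_ref)
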