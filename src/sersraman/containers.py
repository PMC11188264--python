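"""Core in-memory containers for single-cell Raman spectra and SERS hyperspectral maps.

All wavenumber coordinates are Raman shifts in cm^-1; all map coordinates are
physical micrometres. Intensities are in arbitrary (detector) units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SpectralAxis",
    "Band",
    "BackgroundModel",
    "CellLineProfile",
    "ReporterModel",
    "EllipseGeometry",
    "RamanSpectrum",
    "LabeledSpectraSet",
    "HyperspectralMap",
]

_BAND_SHAPES = ("lorentzian", "gaussian")


@dataclass(frozen=True)
class SpectralAxis:
    """A strictly increasing grid of Raman shifts (cm^-1)."""

    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("spectral axis needs at least 2 wavenumbers")
        if not np.all(np.isfinite(w)):
            raise ValueError("spectral axis contains non-finite values")
        if not np.all(np.diff(w) > 0):
            raise ValueError("spectral axis must be strictly increasing")
        object.__setattr__(self, "wavenumbers", w)

    @classmethod
    def from_range(cls, lo: float, hi: float, step: float) -> "SpectralAxis":
        if step <= 0 or hi <= lo:
            raise ValueError("require lo < hi and step > 0")
        n = int(round((hi - lo) / step)) + 1
        return cls(lo + step * np.arange(n))

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def lo(self) -> float:
        return float(self.wavenumbers[0])

    @property
    def hi(self) -> float:
        return float(self.wavenumbers[-1])

    @property
    def spacing(self) -> float:
        """Median channel spacing (cm^-1)."""
        return float(np.median(np.diff(self.wavenumbers)))

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask for channels in the closed interval [lo, hi]."""
        mask = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        if not mask.any():
            raise ValueError(f"empty range: [{lo}, {hi}] contains no channel "
                             f"of axis [{self.lo}, {self.hi}]")
        return mask

    def contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi


@dataclass(frozen=True)
class Band:
    """One vibrational band: a Lorentzian or Gaussian line.

    ``amplitude`` is the peak height at ``center``; ``fwhm`` the full width at
    half maximum.
    """

    center: float
    fwhm: float
    amplitude: float
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("band fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")
        if self.shape not in _BAND_SHAPES:
            raise ValueError(f"unknown band shape {self.shape!r}; "
                             f"expected one of {_BAND_SHAPES}")

    def profile(self, axis: SpectralAxis) -> np.ndarray:
        """Evaluate the line shape on the axis."""
        x = axis.wavenumbers - self.center
        if self.shape == "lorentzian":
            g = self.fwhm / 2.0
            return self.amplitude * g * g / (x * x + g * g)
        # gaussian
        return self.amplitude * np.exp(-4.0 * np.log(2.0) * x * x / self.fwhm**2)


@dataclass(frozen=True)
class BackgroundModel:
    """Autofluorescence + broad water background with additive detector noise.

    Autofluorescence decays exponentially with Raman shift,
    ``fluor_amplitude * exp(-(nu - nu0) / fluor_decay)`` with ``nu0`` the first
    axis value.  The water contribution is a single broad band centred by
    default at 3200 cm^-1 (its main band spans ~2500-3500 cm^-1, so the tail
    reaches into the cropped fingerprint/CH range).  ``noise_sd`` is the
    per-channel standard deviation of additive shot-like noise.
    """

    fluor_amplitude: float = 0.0
    fluor_decay: float = 1200.0
    water_amplitude: float = 0.0
    water_center: float = 3200.0
    water_fwhm: float = 450.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.fluor_amplitude, self.water_amplitude, self.noise_sd) < 0:
            raise ValueError("background amplitudes and noise_sd must be >= 0")
        if self.fluor_decay <= 0 or self.water_fwhm <= 0:
            raise ValueError("fluor_decay and water_fwhm must be > 0")

    def evaluate(self, axis: SpectralAxis) -> np.ndarray:
        """Noise-free background on the axis (fluorescence + water band)."""
        w = axis.wavenumbers
        out = self.fluor_amplitude * np.exp(-(w - w[0]) / self.fluor_decay)
        if self.water_amplitude > 0:
            water = Band(self.water_center, self.water_fwhm,
                         self.water_amplitude, shape="gaussian")
            out = out + water.profile(axis)
        return out


@dataclass(frozen=True)
class CellLineProfile:
    """Generative fingerprint for one simulated cell class."""

    name: str
    bands: tuple[Band, ...]
    background: BackgroundModel = field(default_factory=BackgroundModel)
    cell_amplitude_cv: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 <= self.cell_amplitude_cv < 1.0):
            raise ValueError("cell_amplitude_cv must lie in [0, 1)")
        object.__setattr__(self, "bands", tuple(self.bands))

    def signal(self, axis: SpectralAxis) -> np.ndarray:
        """Sum of all band profiles (no background, no noise)."""
        out = np.zeros(len(axis))
        for band in self.bands:
            out += band.profile(axis)
        return out

    def with_amplitudes(self, scale: float) -> "CellLineProfile":
        bands = tuple(replace(b, amplitude=b.amplitude * scale) for b in self.bands)
        return replace(self, bands=bands)


@dataclass(frozen=True)
class ReporterModel:
    """SERS reporter (4-MBA-like): two aromatic-ring bands whose height scales
    with the local marker density."""

    band_centers: tuple[float, float] = (1080.0, 1580.0)
    band_fwhm: float = 12.0
    gain: float = 1.0
    saturation: float | None = None

    def __post_init__(self) -> None:
        if self.band_fwhm <= 0 or self.gain < 0:
            raise ValueError("band_fwhm must be > 0 and gain >= 0")
        if self.saturation is not None and self.saturation <= 0:
            raise ValueError("saturation must be positive when given")

    def amplitude(self, density: np.ndarray | float) -> np.ndarray | float:
        amp = self.gain * np.asarray(density, dtype=float)
        if self.saturation is not None:
            amp = np.minimum(amp, self.saturation)
        return amp

    def spectrum(self, axis: SpectralAxis, density: float) -> np.ndarray:
        amp = float(self.amplitude(density))
        out = np.zeros(len(axis))
        for c in self.band_centers:
            out += Band(c, self.band_fwhm, amp).profile(axis)
        return out


@dataclass(frozen=True)
class EllipseGeometry:
    """Axis-aligned elliptical cell footprint in micrometres."""

    cx_um: float
    cy_um: float
    rx_um: float
    ry_um: float

    def __post_init__(self) -> None:
        if self.rx_um <= 0 or self.ry_um <= 0:
            raise ValueError("ellipse radii must be positive")

    def mask(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        """Boolean mask on a meshgrid of pixel coordinates."""
        return (((x_um - self.cx_um) / self.rx_um) ** 2
                + ((y_um - self.cy_um) / self.ry_um) ** 2) <= 1.0


@dataclass(frozen=True)
class RamanSpectrum:
    """One spectrum: axis + intensity + free-form metadata."""

    axis: SpectralAxis
    intensity: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        y = np.asarray(self.intensity, dtype=float)
        if y.shape != (len(self.axis),):
            raise ValueError("intensity length must equal axis length")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensity contains non-finite values")
        object.__setattr__(self, "intensity", y)
        object.__setattr__(self, "meta", dict(self.meta))

    def replace_intensity(self, intensity: np.ndarray,
                          axis: SpectralAxis | None = None) -> "RamanSpectrum":
        return RamanSpectrum(axis or self.axis, intensity, self.meta)


class LabeledSpectraSet:
    """A spectra matrix with per-spectrum class and cell-of-origin labels.

    Rows are spectra, columns are wavenumber channels.  ``class_labels`` may be
    ``None`` for unlabeled data (classification stages refuse such sets).
    Invariant: every ``cell_id`` belongs to exactly one class.
    """

    def __init__(self, axis: SpectralAxis, intensities: np.ndarray,
                 class_labels: Sequence[str] | None = None,
                 cell_ids: Sequence[str] | None = None) -> None:
        X = np.asarray(intensities, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(axis):
            raise ValueError("intensities must be (n_spectra, n_channels) "
                             "with n_channels equal to the axis length")
        if not np.all(np.isfinite(X)):
            raise ValueError("intensities contain non-finite values")
        n = X.shape[0]
        if class_labels is not None:
            class_labels = np.asarray(class_labels, dtype=object)
            if class_labels.shape != (n,):
                raise ValueError("one class label per spectrum required")
        if cell_ids is None:
            cell_ids = np.asarray([f"cell{i:05d}" for i in range(n)], dtype=object)
        else:
            cell_ids = np.asarray(cell_ids, dtype=object)
            if cell_ids.shape != (n,):
                raise ValueError("one cell_id per spectrum required")
        if class_labels is not None:
            mapping: dict[object, object] = {}
            for cid, lab in zip(cell_ids, class_labels):
                if mapping.setdefault(cid, lab) != lab:
                    raise ValueError(f"cell_id {cid!r} maps to more than one class")
        self.axis = axis
        self.intensities = X
        self.class_labels = class_labels
        self.cell_ids = cell_ids

    # -- basic introspection -------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return int(self.intensities.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.intensities.shape[1])

    @property
    def classes(self) -> np.ndarray:
        if self.class_labels is None:
            raise ValueError("spectra set has no class labels")
        return np.unique(self.class_labels.astype(str))

    def require_labels(self) -> np.ndarray:
        if self.class_labels is None:
            raise ValueError("operation requires class labels but the set is unlabeled")
        return self.class_labels

    def subset(self, index: np.ndarray) -> "LabeledSpectraSet":
        labels = None if self.class_labels is None else self.class_labels[index]
        return LabeledSpectraSet(self.axis, self.intensities[index],
                                 labels, self.cell_ids[index])

    def spectrum(self, i: int) -> RamanSpectrum:
        meta = {"cell_id": self.cell_ids[i]}
        if self.class_labels is not None:
            meta["class_label"] = self.class_labels[i]
        return RamanSpectrum(self.axis, self.intensities[i], meta)

    def with_matrix(self, intensities: np.ndarray,
                    axis: SpectralAxis | None = None) -> "LabeledSpectraSet":
        return LabeledSpectraSet(axis or self.axis, intensities,
                                 self.class_labels, self.cell_ids)


class HyperspectralMap:
    """A rectangular grid of per-pixel SERS spectra.

    ``cube`` has shape ``(ny, nx, n_channels)``.  Pixel (ix, iy) sits at
    physical position ``(ix * step_um, iy * step_um)``.  ``truth_density`` is
    the simulation-only per-pixel marker density ground truth (zero outside
    the cell mask), ``None`` for measured data.
    """

    def __init__(self, axis: SpectralAxis, cube: np.ndarray, step_um: float,
                 cell_mask: np.ndarray | None = None,
                 truth_density: np.ndarray | None = None) -> None:
        cube = np.asarray(cube, dtype=float)
        if cube.ndim != 3 or cube.shape[2] != len(axis):
            raise ValueError("cube must be (ny, nx, n_channels) matching the axis")
        if step_um <= 0:
            raise ValueError("step_um must be > 0")
        ny, nx = cube.shape[:2]
        if cell_mask is not None:
            cell_mask = np.asarray(cell_mask, dtype=bool)
            if cell_mask.shape != (ny, nx):
                raise ValueError("cell_mask shape must be (ny, nx)")
        if truth_density is not None:
            truth_density = np.asarray(truth_density, dtype=float)
            if truth_density.shape != (ny, nx):
                raise ValueError("truth_density shape must be (ny, nx)")
            if cell_mask is not None and np.any(truth_density[~cell_mask] != 0):
                raise ValueError("truth_density must be zero outside the cell mask")
        self.axis = axis
        self.cube = cube
        self.step_um = float(step_um)
        self.cell_mask = cell_mask
        self.truth_density = truth_density

    @property
    def nx(self) -> int:
        return int(self.cube.shape[1])

    @property
    def ny(self) -> int:
        return int(self.cube.shape[0])

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny

    def pixel_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """(x_um, y_um) meshgrids of pixel positions."""
        x = np.arange(self.nx) * self.step_um
        y = np.arange(self.ny) * self.step_um
        return np.meshgrid(x, y)
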