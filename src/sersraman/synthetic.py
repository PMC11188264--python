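"""Synthetic single-cell Raman spectra and SERS hyperspectral maps.

The generators produce data with a known ground truth so that every
downstream stage — baseline correction, chemometric classification, and
bright-pixel biomarker quantification — can be exercised and validated
without any measured input.

The Raman arm builds class fingerprints from a dictionary of literature band
assignments for breast epithelial cells (aromatic amino-acid bands such as
phenylalanine 1002-1004 cm^-1 and tryptophan ~877 cm^-1, phospholipid/protein
bands at 1081-1096, 1448-1453, 1657-1660 and the 2850-2950 CH-stretch region).
Three default classes mimic the canonical contrast pattern of breast cell
lines: a triple-negative-like class with the highest aromatic amino-acid
content, a HER2-overexpressing-like class with the highest phospholipid and
lipid content, and a non-tumorigenic class with the lowest macromolecule
amplitudes overall.

The SERS arm places a reporter with two aromatic-ring bands (1080 and
1580 cm^-1, the 4-MBA signature) on an elliptical cell footprint, with
per-pixel reporter amplitude proportional to a ground-truth marker density.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .containers import (
    BackgroundModel,
    Band,
    CellLineProfile,
    EllipseGeometry,
    HyperspectralMap,
    LabeledSpectraSet,
    RamanSpectrum,
    ReporterModel,
    SpectralAxis,
)

__all__ = [
    "RAMAN_BAND_TABLE",
    "band_assignment",
    "validate_profile",
    "make_default_profiles",
    "simulate_spectrum",
    "simulate_raman_dataset",
    "simulate_sers_map",
    "simulate_sers_condition",
    "default_raman_axis",
    "default_sers_axis",
    "default_cell_geometry",
]

# Band dictionary: (lo, hi, assignment) intervals in cm^-1 for normal breast
# epithelium and breast-cancer cells.  A profile band is conformant when its
# center falls inside one of these intervals.
RAMAN_BAND_TABLE: tuple[tuple[float, float, str], ...] = (
    (850, 880, "Ring breathing of tyrosine, C-C stretch of proline ring, collagen"),
    (876, 877, "Tryptophan, proteins; antisym. stretching in phosphatidylcholine, lipids"),
    (898, 902, "C-O-C, C-C skeletal modes"),
    (935, 950, "Proline, C-C skeletal of collagen backbone, polysaccharides"),
    (986, 986, "C-C / C-O stretching in ribose"),
    (1002, 1004, "Phenylalanine; CH3 rocking coupled with C-C stretching of carotenoids"),
    (1033, 1033, "C-H in-plane bending of phenylalanine"),
    (1062, 1063, "Chain C-C stretch in lipids; C-O, C-N stretch in proteins; O-P-O in DNA/RNA"),
    (1081, 1096, "O-P-O symmetric stretch of phosphodiesters; C-C lipids; P-O phospholipids"),
    (1125, 1126, "C-C stretching in lipids; C-N in proteins; C-O in glucose"),
    (1155, 1157, "C-C (and C-N) stretching of proteins and carotenoids"),
    (1174, 1176, "C-H in-plane bending of tyrosine and carotenoids"),
    (1207, 1209, "Stretching mode of phenylalanine, tyrosine, hydroxyproline"),
    (1254, 1259, "Amide III, adenine, cytosine (protein beta-sheet)"),
    (1268, 1278, "Amide III (alpha-helix), collagen"),
    (1298, 1303, "CH2 twisting of lipids, phospholipids and fatty acids"),
    (1310, 1310, "CH3/CH2 twisting mode of collagen/lipids"),
    (1317, 1318, "CH2 twist and bend (nucleic acids, proteins, lipids)"),
    (1335, 1342, "CH3/CH2 wagging of collagen; CH2 twist and bend (nucleic acids, proteins)"),
    (1448, 1453, "CH2 bending of proteins; asym. CH3 bending, CH2 scissoring (phospholipids)"),
    (1582, 1582, "Pyrimidine ring (nucleic acids) and heme proteins"),
    (1606, 1620, "Aromatic amino acids, C=C stretching of tyrosine and tryptophan"),
    (1627, 1700, "Amide I"),
    (1657, 1660, "Aromatic amino acids in proteins; C=C olefinic stretch, unsaturated fatty acids"),
    (1730, 1750, "C=O symmetric; glycans and glycogen"),
    (2850, 2875, "CH2 symmetric stretch of lipids; CH2 asymmetric stretch of lipids + proteins"),
    (2885, 2908, "CH2 asymmetric stretch of lipids and proteins"),
    (2945, 2957, "CH3 asymmetric stretch of proteins; aliphatic/aromatic CH in nucleic acids"),
)


def band_assignment(center: float) -> str | None:
    """Return the band-table assignment containing ``center``, or ``None``."""
    for lo, hi, name in RAMAN_BAND_TABLE:
        if lo <= center <= hi:
            return name
    return None


def validate_profile(profile: CellLineProfile) -> list[Band]:
    """Bands of ``profile`` whose center falls in no band-table interval."""
    return [b for b in profile.bands if band_assignment(b.center) is None]


def default_raman_axis() -> SpectralAxis:
    """Acquisition axis 600-3400 cm^-1 at 2 cm^-1 (cropping to 800-3100 is a
    real downstream operation)."""
    return SpectralAxis.from_range(600.0, 3400.0, 2.0)


def default_sers_axis() -> SpectralAxis:
    """SERS acquisition axis 600-1700 cm^-1 at 2 cm^-1."""
    return SpectralAxis.from_range(600.0, 1700.0, 2.0)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Default cell-line profiles
# ---------------------------------------------------------------------------

# Per-band peak amplitudes (a.u.) for (normal, HER2-high, triple-negative).
# Aromatic amino-acid bands are ranked TN > HER2-high > normal; phospholipid /
# lipid / protein bands HER2-high > TN > normal; the normal class has the
# lowest macromolecule amplitudes overall.
_DEFAULT_BANDS: tuple[tuple[float, float, tuple[float, float, float]], ...] = (
    # center, fwhm, (normal, her2_high, triple_negative)
    (877.0, 14.0, (0.20, 0.32, 0.50)),     # tryptophan (aromatic)
    (940.0, 16.0, (0.10, 0.14, 0.13)),
    (1003.0, 10.0, (0.45, 0.70, 1.00)),    # phenylalanine (aromatic)
    (1033.0, 12.0, (0.12, 0.18, 0.26)),    # phenylalanine (aromatic)
    (1085.0, 18.0, (0.25, 0.55, 0.38)),    # phosphodiesters / phospholipids
    (1125.0, 14.0, (0.12, 0.20, 0.16)),
    (1256.0, 24.0, (0.20, 0.30, 0.28)),    # amide III
    (1300.0, 20.0, (0.18, 0.30, 0.24)),    # CH2 twist, lipids
    (1340.0, 22.0, (0.15, 0.26, 0.24)),
    (1450.0, 20.0, (0.40, 0.75, 0.55)),    # CH2 bending, proteins/phospholipids
    (1582.0, 14.0, (0.10, 0.18, 0.16)),
    (1610.0, 16.0, (0.15, 0.24, 0.38)),    # aromatic amino acids
    (1660.0, 28.0, (0.50, 0.90, 0.68)),    # amide I / unsaturated fatty acids
    (2855.0, 45.0, (0.35, 0.80, 0.55)),    # CH2 symmetric stretch, lipids
    (2900.0, 50.0, (0.45, 0.85, 0.62)),    # CH2 asymmetric stretch
    (2950.0, 45.0, (0.40, 0.60, 0.50)),    # CH3 stretch, proteins
)

_DEFAULT_BACKGROUNDS = {
    "normal": BackgroundModel(fluor_amplitude=0.40, fluor_decay=1200.0,
                              water_amplitude=0.25, noise_sd=0.005),
    "her2_high": BackgroundModel(fluor_amplitude=0.60, fluor_decay=1200.0,
                                 water_amplitude=0.25, noise_sd=0.005),
    "triple_negative": BackgroundModel(fluor_amplitude=0.50, fluor_decay=1200.0,
                                       water_amplitude=0.25, noise_sd=0.005),
}


def make_default_profiles(cell_amplitude_cv: float = 0.10,
                          noise_sd: float | None = None) -> list[CellLineProfile]:
    """The three default cell classes: HER2-high, triple-negative, normal.

    All three share the same band centers (each inside a band-table interval)
    and differ only in per-band amplitudes and background level.  ``noise_sd``
    overrides the default per-channel noise (0.005 a.u.) for all classes.
    """
    order = ("her2_high", "triple_negative", "normal")
    column = {"normal": 0, "her2_high": 1, "triple_negative": 2}
    profiles = []
    for name in order:
        bg = _DEFAULT_BACKGROUNDS[name]
        if noise_sd is not None:
            bg = BackgroundModel(bg.fluor_amplitude, bg.fluor_decay,
                                 bg.water_amplitude, bg.water_center,
                                 bg.water_fwhm, noise_sd)
        bands = tuple(Band(c, w, amps[column[name]])
                      for c, w, amps in _DEFAULT_BANDS)
        profiles.append(CellLineProfile(name=name, bands=bands, background=bg,
                                        cell_amplitude_cv=cell_amplitude_cv))
    return profiles


# ---------------------------------------------------------------------------
# Raman forward model
# ---------------------------------------------------------------------------

def simulate_spectrum(profile: CellLineProfile, axis: SpectralAxis,
                      cell_scale: float = 1.0,
                      rng_seed=None) -> RamanSpectrum:
    """Draw one spectrum from the forward model.

    intensity = cell_scale * sum(band profiles) + autofluorescence
                + water band + N(0, noise_sd) per channel.
    """
    rng = _as_rng(rng_seed)
    bg = profile.background
    y = cell_scale * profile.signal(axis) + bg.evaluate(axis)
    if bg.noise_sd > 0:
        y = y + rng.normal(0.0, bg.noise_sd, size=len(axis))
    return RamanSpectrum(axis, y, {"class_label": profile.name,
                                   "cell_scale": cell_scale})


def simulate_raman_dataset(profiles: Sequence[CellLineProfile],
                           n_cells: int = 30,
                           spectra_per_cell: int = 9,
                           axis: SpectralAxis | None = None,
                           rng_seed=None) -> LabeledSpectraSet:
    """Simulate ``len(profiles) * n_cells * spectra_per_cell`` labeled spectra.

    One multiplicative amplitude scale is drawn per cell (lognormal, mean 1,
    coefficient of variation ``profile.cell_amplitude_cv``) and shared by all
    of that cell's spectra, mimicking cell-to-cell overall-intensity
    variability.
    """
    if not profiles:
        raise ValueError("need at least one cell-line profile")
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("profile names must be unique")
    if n_cells < 1 or spectra_per_cell < 1:
        raise ValueError("n_cells and spectra_per_cell must be >= 1")
    axis = axis or default_raman_axis()
    rng = _as_rng(rng_seed)

    rows, labels, cells = [], [], []
    for profile in profiles:
        cv = profile.cell_amplitude_cv
        if cv > 0:
            sigma = float(np.sqrt(np.log1p(cv * cv)))
            mu = -0.5 * sigma * sigma  # mean-1 lognormal
        for j in range(n_cells):
            scale = float(rng.lognormal(mu, sigma)) if cv > 0 else 1.0
            cid = f"{profile.name}-c{j:03d}"
            for _ in range(spectra_per_cell):
                spec = simulate_spectrum(profile, axis, scale, rng)
                rows.append(spec.intensity)
                labels.append(profile.name)
                cells.append(cid)
    return LabeledSpectraSet(axis, np.asarray(rows), labels, cells)


# ---------------------------------------------------------------------------
# SERS forward model
# ---------------------------------------------------------------------------

def default_cell_geometry(nx: int, ny: int, step_um: float) -> EllipseGeometry:
    """A centred ellipse covering roughly half the grid."""
    return EllipseGeometry(cx_um=0.5 * (nx - 1) * step_um,
                           cy_um=0.5 * (ny - 1) * step_um,
                           rx_um=0.34 * nx * step_um,
                           ry_um=0.28 * ny * step_um)


def _density_field(mask: np.ndarray, density_scale: float, mode: str,
                   rho: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-pixel marker density, zero outside the mask.

    ``bernoulli`` (default): each pixel is occupied by a bound nanoprobe
    cluster with probability ``density_scale`` — the dilute limit of discrete
    binding events, under which the expected bright-pixel count is exactly
    proportional to the underlying marker density.
    ``poisson``: each pixel holds a Poisson number of clusters with mean
    ``density_scale`` (occupancy saturates at high density).
    ``uniform``: constant density ``density_scale`` inside the mask.
    ``rim``: Bernoulli occupancy whose probability increases towards the mask
    boundary (membrane staining), mean over the mask ``density_scale``.
    """
    density = np.zeros(mask.shape)
    if density_scale < 0:
        raise ValueError("density_scale must be >= 0")
    if not mask.any() or density_scale == 0:
        return density
    if mode == "uniform":
        density[mask] = density_scale
    elif mode == "bernoulli":
        if density_scale > 1:
            raise ValueError("bernoulli occupancy needs density_scale <= 1")
        density[mask] = (rng.random(int(mask.sum())) < density_scale).astype(float)
    elif mode == "poisson":
        density[mask] = rng.poisson(density_scale, size=int(mask.sum()))
    elif mode == "rim":
        weight = 0.2 + rho[mask] ** 2          # heavier towards rho = 1
        prob = np.clip(density_scale * weight * (weight.size / weight.sum()),
                       0.0, 1.0)
        density[mask] = (rng.random(prob.size) < prob).astype(float)
    else:
        raise ValueError(f"unknown density mode {mode!r}")
    return density


def simulate_sers_map(nx: int, ny: int, step_um: float = 1.0,
                      axis: SpectralAxis | None = None,
                      cell_geometry: EllipseGeometry | None = None,
                      density_scale: float = 0.4,
                      reporter: ReporterModel | None = None,
                      noise_sd: float = 0.02,
                      rng_seed=None,
                      density_mode: str = "bernoulli") -> HyperspectralMap:
    """Simulate one single-cell SERS map on an ``nx`` x ``ny`` grid.

    Pixels inside the cell mask carry the reporter doublet with amplitude
    ``gain * density`` on top of the noise floor; pixels outside carry noise
    only.  The drawn density field is stored as ``truth_density``.
    """
    axis = axis or default_sers_axis()
    reporter = reporter or ReporterModel()
    for c in reporter.band_centers:
        if not axis.contains(c):
            raise ValueError(f"reporter band {c} cm^-1 outside the map axis "
                             f"[{axis.lo}, {axis.hi}]")
    geom = cell_geometry or default_cell_geometry(nx, ny, step_um)
    x_max, y_max = (nx - 1) * step_um, (ny - 1) * step_um
    if (geom.cx_um - geom.rx_um < 0 or geom.cx_um + geom.rx_um > x_max
            or geom.cy_um - geom.ry_um < 0 or geom.cy_um + geom.ry_um > y_max):
        raise ValueError("cell geometry does not fit inside the map grid")
    rng = _as_rng(rng_seed)

    x_um, y_um = np.meshgrid(np.arange(nx) * step_um, np.arange(ny) * step_um)
    mask = geom.mask(x_um, y_um)
    rho = np.sqrt(((x_um - geom.cx_um) / geom.rx_um) ** 2
                  + ((y_um - geom.cy_um) / geom.ry_um) ** 2)
    density = _density_field(mask, density_scale, density_mode, rho, rng)

    n_chan = len(axis)
    cube = (rng.normal(0.0, noise_sd, size=(ny, nx, n_chan))
            if noise_sd > 0 else np.zeros((ny, nx, n_chan)))
    doublet = np.zeros(n_chan)
    for c in reporter.band_centers:
        doublet += Band(c, reporter.band_fwhm, 1.0).profile(axis)
    amp = np.asarray(reporter.amplitude(density))
    hot = amp > 0
    if hot.any():
        cube[hot] += amp[hot, None] * doublet[None, :]
    return HyperspectralMap(axis, cube, step_um, cell_mask=mask,
                            truth_density=density)


def simulate_sers_condition(n_cells: int, density_scale: float,
                            nx: int = 30, ny: int = 30, step_um: float = 1.0,
                            axis: SpectralAxis | None = None,
                            reporter: ReporterModel | None = None,
                            noise_sd: float = 0.02,
                            rng_seed=None,
                            density_mode: str = "bernoulli") -> list[HyperspectralMap]:
    """One map per cell for a whole experimental condition."""
    rng = _as_rng(rng_seed)
    return [simulate_sers_map(nx, ny, step_um, axis, None, density_scale,
                              reporter, noise_sd, rng, density_mode)
            for _ in range(n_cells)]
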