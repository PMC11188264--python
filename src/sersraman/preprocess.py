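"""Spectral preprocessing chain for single-cell Raman spectra.

Fixed stage order: crop to the informative range (default 800-3100 cm^-1,
which removes most of the broad water band above 3100 cm^-1), subtract a
rubber-band baseline (smoothing spline through the lower-convex-hull support
points; removes autofluorescence and the remaining water tail), subtract a
residual asymmetric-least-squares (Whittaker) baseline, optionally rebin to a
coarser resolution for discriminant analysis, and finally scale each spectrum
to unit Euclidean norm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.interpolate import CubicSpline
from scipy.linalg import solveh_banded

from .containers import LabeledSpectraSet, RamanSpectrum, SpectralAxis

__all__ = [
    "PreprocessConfig",
    "AlsResult",
    "crop",
    "lower_hull_indices",
    "rubberband_baseline",
    "als_baseline",
    "vector_normalize",
    "rebin",
    "preprocess_pipeline",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``als_lambda`` is the second-difference smoothness weight, ``als_p`` the
    asymmetry weight (< 0.5 keeps the baseline under the peaks).
    ``rebin_width`` (cm^-1) is applied only when ``rebin`` is true — the
    coarse grid is used for the discriminant-analysis branch only, while PCA
    runs at native resolution.
    """

    crop_lo: float = 800.0
    crop_hi: float = 3100.0
    als_lambda: float = 1e5
    als_p: float = 0.001
    als_iters: int = 10
    als_tol: float = 1e-6
    rebin_width: float = 6.0
    rebin: bool = False
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.crop_lo >= self.crop_hi:
            raise ValueError("crop_lo must be < crop_hi")
        if self.als_lambda <= 0:
            raise ValueError("als_lambda must be > 0")
        if not (0.0 < self.als_p < 1.0):
            raise ValueError("als_p must lie in (0, 1)")
        if self.als_p >= 0.5:
            warnings.warn("als_p >= 0.5 does not produce a lower baseline",
                          stacklevel=2)

    def for_lda(self) -> "PreprocessConfig":
        return replace(self, rebin=True)


def crop(spectrum: RamanSpectrum, lo: float, hi: float) -> RamanSpectrum:
    """Restrict a spectrum to the closed wavenumber interval [lo, hi]."""
    mask = spectrum.axis.window_mask(lo, hi)
    axis = SpectralAxis(spectrum.axis.wavenumbers[mask])
    return spectrum.replace_intensity(spectrum.intensity[mask], axis)


# ---------------------------------------------------------------------------
# Rubber-band baseline
# ---------------------------------------------------------------------------

def lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull vertices of the polyline (x, y).

    Monotone-chain construction; x must be strictly increasing.  Collinear
    interior points are dropped, so a straight-line spectrum reduces to its
    two endpoints.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            cross = ((x[a] - x[o]) * (y[i] - y[o])
                     - (y[a] - y[o]) * (x[i] - x[o]))
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def rubberband_baseline(spectrum: RamanSpectrum) -> np.ndarray:
    """Baseline through the lower-convex-hull support points.

    The support points are the vertices of the lower convex hull of
    (wavenumber, intensity); the baseline is a spline through them (cubic
    interpolating spline — smoothing parameter zero — falling back to linear
    interpolation when fewer than four support points exist).  The baseline
    equals the spectrum at every support point and therefore never exceeds
    it there.
    """
    x = spectrum.axis.wavenumbers
    y = spectrum.intensity
    if x.size < 3:
        raise ValueError("rubber-band baseline needs at least 3 channels")
    idx = lower_hull_indices(x, y)
    if idx.size < 4:
        return np.interp(x, x[idx], y[idx])
    return CubicSpline(x[idx], y[idx])(x)


# ---------------------------------------------------------------------------
# Asymmetric least squares (Whittaker) baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlsResult:
    baseline: np.ndarray
    n_iter: int
    converged: bool


def _second_difference_penalty(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diagonals (main, +1, +2) of D2' D2 for the n-point second difference."""
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    P = (D.T @ D).todia()
    return P.diagonal(0), P.diagonal(1), P.diagonal(2)


def als_baseline(y: np.ndarray | RamanSpectrum,
                 lam: float = 1e5, p: float = 0.001,
                 max_iter: int = 10, tol: float = 1e-6) -> AlsResult:
    """Asymmetric-least-squares baseline (Whittaker smoother with asymmetric
    weights).

    The baseline z minimizes ``sum_i w_i (y_i - z_i)^2 + lam * sum (D2 z)^2``
    with weights iteratively set to ``p`` where ``y > z`` and ``1 - p``
    elsewhere, starting from uniform weights.  Iteration stops when the
    weights change by at most ``tol`` or after ``max_iter`` rounds; running
    out of iterations raises a warning flag, not an error.

    Each inner solve uses the symmetric pentadiagonal system directly
    (Cholesky-banded), so the fit is exact at the current weights.
    """
    if isinstance(y, RamanSpectrum):
        y = y.intensity
    y = np.asarray(y, float)
    n = y.size
    if n < 3:
        raise ValueError("ALS baseline needs at least 3 channels")
    if lam <= 0 or not (0.0 < p < 1.0):
        raise ValueError("require lam > 0 and 0 < p < 1")
    d0, d1, d2 = _second_difference_penalty(n)
    ab = np.zeros((3, n))
    ab[0, 2:] = lam * d2
    ab[1, 1:] = lam * d1
    w = np.ones(n)
    z_prev = None
    converged = False
    n_iter = 0
    scale = float(np.max(np.abs(y))) or 1.0
    for n_iter in range(1, max_iter + 1):
        ab[2, :] = lam * d0 + w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, p, 1.0 - p)
        # converged when either the weights or the baseline itself stabilize
        # (the weight rule can flip forever on floating-point ties)
        if (np.max(np.abs(w_new - w)) <= tol
                or (z_prev is not None
                    and np.max(np.abs(z - z_prev)) <= tol * scale)):
            converged = True
            break
        w, z_prev = w_new, z
    if not converged:
        warnings.warn(f"ALS weights did not converge in {max_iter} iterations",
                      stacklevel=2)
    return AlsResult(baseline=z, n_iter=n_iter, converged=converged)


# ---------------------------------------------------------------------------
# Normalization and rebinning
# ---------------------------------------------------------------------------

def vector_normalize(spectrum: RamanSpectrum) -> RamanSpectrum:
    """Scale the intensity vector to unit Euclidean norm."""
    norm = float(np.linalg.norm(spectrum.intensity))
    if norm == 0.0:
        raise ValueError("cannot vector-normalize a zero-norm spectrum")
    return spectrum.replace_intensity(spectrum.intensity / norm)


def _bin_layout(axis: SpectralAxis, width: float,
                anchor: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(bin start indices into the axis, bin-center wavenumbers).

    Contiguous half-open bins [anchor + k*width, anchor + (k+1)*width),
    anchored at the first axis value by default.
    """
    x = axis.wavenumbers
    native = float(np.min(np.diff(x)))
    if width < native - 1e-9:
        raise ValueError(f"rebin width {width} cm^-1 is below the native "
                         f"spacing {native} cm^-1")
    x0 = axis.lo if anchor is None else anchor
    k = np.floor((x - x0) / width + 1e-9).astype(int)
    starts = np.flatnonzero(np.r_[True, np.diff(k) != 0])
    centers = x0 + (k[starts] + 0.5) * width
    return starts, centers


def rebin(spectrum: RamanSpectrum, width: float,
          anchor: float | None = None) -> RamanSpectrum:
    """Average channels into contiguous half-open bins of the given width."""
    starts, centers = _bin_layout(spectrum.axis, width, anchor)
    counts = np.diff(np.r_[starts, len(spectrum.axis)])
    values = np.add.reduceat(spectrum.intensity, starts) / counts
    return spectrum.replace_intensity(values, SpectralAxis(centers))


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def preprocess_pipeline(sset: LabeledSpectraSet,
                        cfg: PreprocessConfig | None = None) -> LabeledSpectraSet:
    """Apply crop -> rubber-band -> ALS -> (optional rebin) -> vector
    normalization to every spectrum of a set; labels are untouched.

    Deterministic (no randomness).  Per-spectrum failures are re-raised with
    the spectrum index; ALS non-convergence is logged, not raised.
    """
    cfg = cfg or PreprocessConfig()
    mask = sset.axis.window_mask(cfg.crop_lo, cfg.crop_hi)
    axis = SpectralAxis(sset.axis.wavenumbers[mask])
    X = sset.intensities[:, mask]

    if cfg.rebin:
        starts, centers = _bin_layout(axis, cfg.rebin_width, anchor=cfg.crop_lo)
        counts = np.diff(np.r_[starts, len(axis)])

    rows = []
    n_als_capped = 0
    for i in range(X.shape[0]):
        try:
            spec = RamanSpectrum(axis, X[i])
            y = spec.intensity - rubberband_baseline(spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                als = als_baseline(y, cfg.als_lambda, cfg.als_p,
                                   cfg.als_iters, cfg.als_tol)
            if not als.converged:
                n_als_capped += 1
                log.debug("spectrum %d: ALS stopped at %d iterations "
                          "without weight convergence", i, als.n_iter)
            y = y - als.baseline
            if cfg.rebin:
                y = np.add.reduceat(y, starts) / counts
            if cfg.normalize:
                norm = float(np.linalg.norm(y))
                if norm == 0.0:
                    raise ValueError("zero-norm spectrum after baseline removal")
                y = y / norm
            rows.append(y)
        except Exception as exc:
            raise type(exc)(f"spectrum {i}: {exc}") from exc
    if n_als_capped:
        log.info("%d of %d spectra hit the ALS iteration cap (%d) before "
                 "weight convergence", n_als_capped, X.shape[0], cfg.als_iters)
    out_axis = SpectralAxis(centers) if cfg.rebin else axis
    return LabeledSpectraSet(out_axis, np.asarray(rows),
                             sset.class_labels, sset.cell_ids)
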