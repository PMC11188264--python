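"""Readers/writers for the on-disk interchange formats and run configuration.

Spectra travel as wide CSV (first column ``wavenumber_cm1``, one column per
spectrum) with a sidecar label table; hyperspectral maps as long CSV with
columns ``x_um, y_um, wavenumber_cm1, intensity`` plus a truth sidecar for
simulated maps.  Reports are JSON with a schema version, a config echo and
the SHA-256 hash of the config that produced them.  All floats are written
with 17 significant digits so round-trips are lossless.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import HyperspectralMap, LabeledSpectraSet, SpectralAxis
from .preprocess import PreprocessConfig

__all__ = [
    "RunConfig",
    "read_spectra",
    "write_spectra",
    "read_map",
    "write_map",
    "write_bright_mask",
    "write_report",
    "config_hash",
]

SCHEMA_VERSION = "1"
_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RamanSimConfig:
    n_cells: int = 30
    spectra_per_cell: int = 9
    axis_lo: float = 600.0
    axis_hi: float = 3400.0
    axis_step: float = 2.0
    cell_amplitude_cv: float = 0.10
    noise_sd: float | None = None   # None = profile default


@dataclass
class SersSimConfig:
    n_cells: int = 30
    nx: int = 30
    ny: int = 30
    step_um: float = 1.0
    axis_lo: float = 600.0
    axis_hi: float = 1700.0
    axis_step: float = 2.0
    density_scale: float = 0.4
    density_mode: str = "bernoulli"
    noise_sd: float = 0.02


@dataclass
class QuantConfig:
    reporter_centers: tuple[float, float] = (1080.0, 1580.0)
    reporter_halfwidth: float = 10.0
    noise_lo: float = 890.0
    noise_hi: float = 910.0


@dataclass
class RunConfig:
    """Top-level configuration: one root seed plus per-stage parameters."""

    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    raman: RamanSimConfig = field(default_factory=RamanSimConfig)
    sers: SersSimConfig = field(default_factory=SersSimConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)

    def __post_init__(self) -> None:
        q, s = self.quant, self.sers
        for c in q.reporter_centers:
            if not (s.axis_lo <= c <= s.axis_hi):
                raise ValueError(f"reporter band {c} outside the SERS axis")
        if not (s.axis_lo <= q.noise_lo < q.noise_hi <= s.axis_hi):
            raise ValueError("noise window outside the SERS axis")
        p = self.preprocess
        if not (self.raman.axis_lo <= p.crop_lo < p.crop_hi <= self.raman.axis_hi):
            raise ValueError("crop window outside the Raman axis")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["quant"]["reporter_centers"] = list(d["quant"]["reporter_centers"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "preprocess" in d:
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "raman" in d:
            d["raman"] = RamanSimConfig(**d["raman"])
        if "sers" in d:
            d["sers"] = SersSimConfig(**d["sers"])
        if "quant" in d:
            q = dict(d["quant"])
            if "reporter_centers" in q:
                q["reporter_centers"] = tuple(q["reporter_centers"])
            d["quant"] = QuantConfig(**q)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig | dict | None) -> str:
    """SHA-256 of the canonical JSON form of a configuration."""
    if config is None:
        payload = {}
    elif isinstance(config, RunConfig):
        payload = config.to_dict()
    else:
        payload = config
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def _labels_path(path: Path) -> Path:
    return path.with_suffix(".labels.csv")


def write_spectra(sset: LabeledSpectraSet, path,
                  labels_path=None) -> tuple[Path, Path | None]:
    """Write a spectra set as wide CSV plus a label sidecar (when labeled)."""
    path = Path(path)
    cols = {"wavenumber_cm1": sset.axis.wavenumbers}
    for i in range(sset.n_spectra):
        cols[f"s{i:05d}"] = sset.intensities[i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)
    lp = None
    if sset.class_labels is not None:
        lp = Path(labels_path) if labels_path else _labels_path(path)
        pd.DataFrame({"spectrum": [f"s{i:05d}" for i in range(sset.n_spectra)],
                      "cell_id": sset.cell_ids,
                      "class_label": sset.class_labels,
                      }).to_csv(lp, index=False)
    return path, lp


def read_spectra(path, labels_path=None, dialect: str = "wide") -> LabeledSpectraSet:
    """Load a spectra set; axis is sorted ascending (with a warning) if the
    file stores descending wavenumbers.  Without a label sidecar the set
    loads unlabeled and classification stages will refuse it."""
    path = Path(path)
    if dialect == "wide":
        df = pd.read_csv(path, float_precision="round_trip")
        if "wavenumber_cm1" not in df.columns:
            raise ValueError("wide spectra CSV needs a 'wavenumber_cm1' column")
        if not df.map(np.isreal).all().all():
            raise ValueError("non-numeric cells in spectra CSV")
        w = df["wavenumber_cm1"].to_numpy(float)
        X = df.drop(columns="wavenumber_cm1").to_numpy(float).T
        names = [c for c in df.columns if c != "wavenumber_cm1"]
    elif dialect == "long":
        df = pd.read_csv(path, float_precision="round_trip")
        wide = df.pivot(index="wavenumber_cm1", columns="spectrum",
                        values="intensity")
        w = wide.index.to_numpy(float)
        X = wide.to_numpy(float).T
        names = list(wide.columns)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if np.unique(w).size != w.size:
        raise ValueError("duplicate wavenumbers in spectra file")
    if np.all(np.diff(w) < 0):
        warnings.warn("wavenumbers stored descending; sorting ascending",
                      stacklevel=2)
        w, X = w[::-1], X[:, ::-1]
    elif not np.all(np.diff(w) > 0):
        order = np.argsort(w)
        warnings.warn("wavenumbers unsorted; sorting ascending", stacklevel=2)
        w, X = w[order], X[:, order]

    labels = cells = None
    lp = Path(labels_path) if labels_path else _labels_path(path)
    if lp.exists():
        lab = pd.read_csv(lp).set_index("spectrum")
        lab = lab.loc[names]
        labels = lab["class_label"].to_numpy(object)
        cells = lab["cell_id"].to_numpy(object)
    return LabeledSpectraSet(SpectralAxis(w), X, labels, cells)


# ---------------------------------------------------------------------------
# Hyperspectral maps
# ---------------------------------------------------------------------------

def _truth_path(path: Path) -> Path:
    return path.with_suffix(".truth.csv")


def write_map(hmap: HyperspectralMap, path, truth_path=None) -> tuple[Path, Path | None]:
    """Write a map as long CSV; simulated maps get a truth sidecar."""
    path = Path(path)
    x_um, y_um = hmap.pixel_coordinates()
    n_chan = len(hmap.axis)
    df = pd.DataFrame({
        "x_um": np.repeat(x_um.ravel(), n_chan),
        "y_um": np.repeat(y_um.ravel(), n_chan),
        "wavenumber_cm1": np.tile(hmap.axis.wavenumbers, hmap.n_pixels),
        "intensity": hmap.cube.reshape(-1),
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    tp = None
    if hmap.truth_density is not None or hmap.cell_mask is not None:
        tp = Path(truth_path) if truth_path else _truth_path(path)
        mask = (hmap.cell_mask if hmap.cell_mask is not None
                else np.zeros((hmap.ny, hmap.nx), bool))
        truth = (hmap.truth_density if hmap.truth_density is not None
                 else np.zeros((hmap.ny, hmap.nx)))
        pd.DataFrame({"x_um": x_um.ravel(), "y_um": y_um.ravel(),
                      "in_cell": mask.ravel().astype(int),
                      "truth_density": truth.ravel(),
                      }).to_csv(tp, index=False, float_format=_FLOAT_FMT)
    return path, tp


def read_map(path, truth_path=None) -> HyperspectralMap:
    """Assemble a dense cube from a long-CSV map; the grid must be complete
    and the pixel step uniform (it is inferred from the coordinates)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    xs = np.unique(df["x_um"].to_numpy(float))
    ys = np.unique(df["y_um"].to_numpy(float))
    ws = np.unique(df["wavenumber_cm1"].to_numpy(float))
    expected = xs.size * ys.size * ws.size
    if len(df) != expected:
        counts = df.groupby(["x_um", "y_um"]).size()
        bad = counts[counts != ws.size]
        where = (f" (pixel x={bad.index[0][0]}, y={bad.index[0][1]})"
                 if len(bad) else "")
        raise ValueError(f"incomplete map grid: {len(df)} rows, expected "
                         f"{expected}{where}")
    for name, coord in (("x", xs), ("y", ys)):
        if coord.size > 1:
            steps = np.diff(coord)
            if not np.allclose(steps, steps[0]):
                raise ValueError(f"non-uniform {name} pixel spacing")
    step = float(np.diff(xs)[0]) if xs.size > 1 else (
        float(np.diff(ys)[0]) if ys.size > 1 else 1.0)
    df = df.sort_values(["y_um", "x_um", "wavenumber_cm1"], kind="mergesort")
    cube = df["intensity"].to_numpy(float).reshape(ys.size, xs.size, ws.size)

    mask = truth = None
    tp = Path(truth_path) if truth_path else _truth_path(path)
    if tp.exists():
        tr = pd.read_csv(tp, float_precision="round_trip").sort_values(["y_um", "x_um"], kind="mergesort")
        mask = tr["in_cell"].to_numpy(int).astype(bool).reshape(ys.size, xs.size)
        truth = tr["truth_density"].to_numpy(float).reshape(ys.size, xs.size)
    return HyperspectralMap(SpectralAxis(ws), cube, step, cell_mask=mask,
                            truth_density=truth)


def write_bright_mask(mask: np.ndarray, step_um: float, path) -> Path:
    """Bright-pixel mask as CSV: x_um, y_um, bright in {0, 1}."""
    path = Path(path)
    ny, nx = mask.shape
    x_um, y_um = np.meshgrid(np.arange(nx) * step_um, np.arange(ny) * step_um)
    pd.DataFrame({"x_um": x_um.ravel(), "y_um": y_um.ravel(),
                  "bright": mask.ravel().astype(int)}).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(results: dict, path, config: RunConfig | dict | None = None) -> Path:
    """Deterministic JSON report: schema version, config echo + hash, results."""
    path = Path(path)
    cfg = (config.to_dict() if isinstance(config, RunConfig)
           else (config or {}))
    payload = {
        "schema_version": SCHEMA_VERSION,
        "config": _jsonable(cfg),
        "config_sha256": config_hash(cfg),
        "results": _jsonable(results),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
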