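"""Quick-look plots: PC/LD score scatters, score box plots, intensity maps."""

from __future__ import annotations

import numpy as np

from .chemometrics import LDAModel, PCAModel
from .containers import LabeledSpectraSet
from .sersquant import IntensityMap

__all__ = ["score_scatter", "score_boxplot", "ld_scatter", "intensity_map_plot"]


def _require_axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def score_scatter(pca: PCAModel, labels, components: tuple[int, int] = (2, 4),
                  ax=None):
    """Scatter of two PC scores (1-based component indices), one colour per
    class."""
    ax = _require_axes(ax)
    i, j = components[0] - 1, components[1] - 1
    labels = np.asarray(labels)
    for cls in np.unique(labels.astype(str)):
        m = labels == cls
        ax.scatter(pca.scores[m, i], pca.scores[m, j], s=8, label=str(cls))
    ax.set_xlabel(f"PC{components[0]} score")
    ax.set_ylabel(f"PC{components[1]} score")
    ax.legend()
    return ax


def score_boxplot(pca: PCAModel, labels, component: int = 4, ax=None):
    """Box plot of one PC's scores per class."""
    ax = _require_axes(ax)
    labels = np.asarray(labels)
    classes = list(np.unique(labels.astype(str)))
    data = [pca.scores[labels == c, component - 1] for c in classes]
    ax.boxplot(data, tick_labels=classes)
    ax.set_ylabel(f"PC{component} score")
    return ax


def ld_scatter(model: LDAModel, sset: LabeledSpectraSet, ax=None):
    """LD1-LD2 scatter of a labeled set under a fitted discriminant model."""
    ax = _require_axes(ax)
    Z = model.transform(sset.intensities)
    labels = sset.require_labels()
    for cls in np.unique(labels.astype(str)):
        m = labels == cls
        if Z.shape[1] > 1:
            ax.scatter(Z[m, 0], Z[m, 1], s=8, label=str(cls))
        else:
            ax.scatter(Z[m, 0], np.zeros(int(m.sum())), s=8, label=str(cls))
    ax.set_xlabel("LD1")
    ax.set_ylabel("LD2" if Z.shape[1] > 1 else "")
    ax.legend()
    return ax


def intensity_map_plot(imap: IntensityMap, ax=None, cmap: str = "inferno"):
    """Colour map of a band-intensity image (pixel coordinates in um)."""
    ax = _require_axes(ax)
    ny, nx = imap.values.shape
    extent = (0, (nx - 1) * imap.step_um, 0, (ny - 1) * imap.step_um)
    im = ax.imshow(imap.values, origin="lower", extent=extent, cmap=cmap)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(f"{imap.band_center:.0f} cm$^{{-1}}$")
    ax.figure.colorbar(im, ax=ax, label="intensity (a.u.)")
    return ax
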