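"""Chemometrics: PCA via SVD, rank-sum tests on component scores, and LDA
classification with a repeated random-subsampling misclassification estimate.

The classification protocol mirrors common single-cell Raman practice: spectra
from one cell never straddle a train/test boundary (cell-grouped splits), the
discriminant model is trained on half the cells, and model stability is
summarized as the mean misclassification error over many random equal-class
test draws of one tenth of the data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from .containers import LabeledSpectraSet

__all__ = [
    "PCAModel",
    "LDAModel",
    "MisclassificationResult",
    "pca_svd",
    "cumulative_variance",
    "p_to_stars",
    "wilcoxon_scores",
    "grouped_split",
    "lda_fit",
    "misclassification_estimate",
]


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, LabeledSpectraSet):
        return data.intensities
    return np.asarray(data, dtype=float)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAModel:
    """Principal components of a spectra matrix.

    ``loadings`` rows are orthonormal channel-weight vectors (component x
    channel); ``scores`` are the centred data projected on them (spectrum x
    component); ``explained_variance_fraction`` is non-increasing and sums to
    1 when all components are kept.  Sign convention: the largest-magnitude
    element of each loading vector is positive.
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return int(self.loadings.shape[0])

    def transform(self, data) -> np.ndarray:
        X = _as_matrix(data)
        return (X - self.mean_spectrum) @ self.loadings.T

    def reconstruct(self) -> np.ndarray:
        return self.mean_spectrum + self.scores @ self.loadings


def pca_svd(data, n_components: int | None = None) -> PCAModel:
    """PCA by singular value decomposition of the mean-centred matrix."""
    X = _as_matrix(data)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 spectra")
    mean = X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
    total = float(np.sum(s * s))
    frac = s * s / total if total > 0 else np.zeros_like(s)
    k = s.size if n_components is None else n_components
    if k > s.size:
        warnings.warn(f"requested {k} components but only {s.size} available; "
                      "truncating", stacklevel=2)
        k = s.size
    U, s, Vt, frac = U[:, :k], s[:k], Vt[:k], frac[:k]
    # deterministic sign: largest-|.| loading element positive
    flip = np.sign(Vt[np.arange(k), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    scores = U * s * flip[None, :]
    return PCAModel(mean_spectrum=mean, loadings=Vt, scores=scores,
                    explained_variance_fraction=frac)


def cumulative_variance(model: PCAModel, k: int) -> float:
    """Total variance fraction explained by the first ``k`` components."""
    if not (1 <= k <= model.n_components):
        raise ValueError(f"k must lie in [1, {model.n_components}]")
    return float(np.sum(model.explained_variance_fraction[:k]))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum tests on component scores
# ---------------------------------------------------------------------------

def p_to_stars(p: float) -> str:
    """Significance stars; four stars flag p < 0.0001."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def wilcoxon_scores(scores: np.ndarray, labels) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test for every class pair of 1-D scores.

    Uses the exact null distribution when the combined sample size is at most
    20 and the data are tie-free, and the normal approximation with tie
    correction (no continuity correction) otherwise.  Holm-adjusted p-values
    are reported alongside the raw ones.
    """
    scores = np.asarray(scores, float).ravel()
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    groups = {g: scores[labels == g] for g in np.unique(labels.astype(str))}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for a, b in itertools.combinations(sorted(groups), 2):
        xa, xb = groups[a], groups[b]
        if xa.size == 0 or xb.size == 0:
            raise ValueError("each group needs at least one observation")
        pooled = np.concatenate([xa, xb])
        ties = np.unique(pooled).size < pooled.size
        method = "exact" if (pooled.size <= 20 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                 method=method, use_continuity=False)
        rows.append({"group_a": a, "group_b": b, "n_a": xa.size, "n_b": xb.size,
                     "statistic": float(res.statistic),
                     "pvalue": float(min(res.pvalue, 1.0)),
                     "method": method})
    table = pd.DataFrame(rows)
    table["pvalue_holm"] = multipletests(table["pvalue"], method="holm")[1]
    table["stars"] = table["pvalue"].map(p_to_stars)
    return table


# ---------------------------------------------------------------------------
# Cell-grouped splitting
# ---------------------------------------------------------------------------

def _cells_by_class(sset: LabeledSpectraSet) -> dict[str, np.ndarray]:
    labels = sset.require_labels()
    return {str(c): np.unique(sset.cell_ids[labels == c])
            for c in sset.classes}


def grouped_split(sset: LabeledSpectraSet, train_fraction: float = 0.5,
                  rng_seed=None) -> tuple[LabeledSpectraSet, LabeledSpectraSet]:
    """Random train/test split at the cell level.

    All spectra of a given cell land on the same side; per class, the train
    cell count equals ``round(train_fraction * n_cells)`` (within one cell of
    the exact fraction).  Both sides must be non-empty for every class.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly between 0 and 1 "
                         "(otherwise one side of the split is empty)")
    rng = np.random.default_rng(rng_seed)
    train_cells: list = []
    for cls, cells in _cells_by_class(sset).items():
        if cells.size < 2:
            raise ValueError(f"class {cls!r} has a single cell; a cell-grouped "
                             "split cannot populate both sides")
        n_train = int(round(train_fraction * cells.size))
        n_train = min(max(n_train, 1), cells.size - 1)
        perm = rng.permutation(cells)
        train_cells.extend(perm[:n_train])
    in_train = np.isin(sset.cell_ids, np.asarray(train_cells, dtype=object))
    return sset.subset(in_train), sset.subset(~in_train)


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    """PCA-reduced Fisher discriminant model.

    Channels greatly outnumber spectra, so the within-class scatter is first
    made well-conditioned by projecting onto the leading principal components
    (capped at ``n_train - n_classes`` components or the number reaching the
    variance cap, whichever is smaller); Fisher discriminants are then
    computed in that reduced space.  ``transform`` returns LD1, LD2, ...
    coordinates; the number of discriminants is ``n_classes - 1``.
    """

    pca: PCAModel
    n_reduced: int
    estimator: LinearDiscriminantAnalysis
    classes: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_discriminants(self) -> int:
        return int(len(self.classes) - 1)

    @property
    def class_means(self) -> np.ndarray:
        return self.estimator.means_

    def _reduce(self, data) -> np.ndarray:
        return self.pca.transform(data)[:, :self.n_reduced]

    def predict(self, data) -> np.ndarray:
        return self.estimator.predict(self._reduce(data))

    def transform(self, data) -> np.ndarray:
        """Latent-variable (LD) coordinates."""
        return self.estimator.transform(self._reduce(data))

    def accuracy(self, data: LabeledSpectraSet) -> float:
        pred = self.predict(data)
        return float(np.mean(pred == data.require_labels().astype(str)))


def lda_fit(train: LabeledSpectraSet, variance_cap: float = 0.99) -> LDAModel:
    """Fit the PCA-reduced LDA on a (preprocessed, typically rebinned) set."""
    y = train.require_labels().astype(str)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("LDA needs at least 2 classes")
    pca = pca_svd(train)
    cum = np.cumsum(pca.explained_variance_fraction)
    k_var = int(np.searchsorted(cum, variance_cap) + 1)
    k = max(1, min(train.n_spectra - classes.size, k_var, pca.n_components))
    est = LinearDiscriminantAnalysis(solver="svd")
    est.fit(pca.scores[:, :k], y)
    return LDAModel(pca=pca, n_reduced=k, estimator=est, classes=classes)


# ---------------------------------------------------------------------------
# Repeated random-subsampling misclassification estimate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MisclassificationResult:
    """Distribution of test errors over repeated random equal-class draws."""

    per_iteration_error: np.ndarray
    n_iterations: int
    test_spectra_per_class: int

    @property
    def mean_error(self) -> float:
        return float(np.mean(self.per_iteration_error))

    @property
    def accuracy(self) -> float:
        return 1.0 - self.mean_error


def misclassification_estimate(sset: LabeledSpectraSet,
                               n_iterations: int = 1000,
                               test_fraction: float = 0.1,
                               rng_seed=None,
                               variance_cap: float = 0.99) -> MisclassificationResult:
    """Mean misclassification error over repeated random test draws.

    Each iteration draws a test subset of roughly ``test_fraction`` of the
    data with exactly equal per-class spectrum counts, grouped by cell (whole
    cells move together), trains the LDA on the remainder and records the
    test error fraction.  Requires a uniform number of spectra per cell so
    that equal per-class counts are reachable by whole cells.
    """
    labels = sset.require_labels().astype(str)
    cells = _cells_by_class(sset)
    n_classes = len(cells)
    _, counts = np.unique(sset.cell_ids, return_counts=True)
    if np.unique(counts).size != 1:
        raise ValueError("equal-class test draws need a uniform number of "
                         "spectra per cell")
    spc = int(counts[0])
    quota = sset.n_spectra * test_fraction / n_classes
    cells_per_class = max(1, int(round(quota / spc)))
    for cls, cc in cells.items():
        if cc.size <= cells_per_class:
            raise ValueError(f"class {cls!r} has too few cells "
                             f"({cc.size}) for a {cells_per_class}-cell test draw")
    rng = np.random.default_rng(rng_seed)
    errors = np.empty(n_iterations)
    for it in range(n_iterations):
        test_cells: list = []
        for cc in cells.values():
            test_cells.extend(rng.choice(cc, size=cells_per_class, replace=False))
        in_test = np.isin(sset.cell_ids, np.asarray(test_cells, dtype=object))
        model = lda_fit(sset.subset(~in_test), variance_cap=variance_cap)
        pred = model.predict(sset.intensities[in_test])
        errors[it] = np.mean(pred != labels[in_test])
    return MisclassificationResult(per_iteration_error=errors,
                                   n_iterations=n_iterations,
                                   test_spectra_per_class=cells_per_class * spc)
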