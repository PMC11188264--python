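"""High-level model interfaces in the model/results style.

``RamanCellClassifier`` wraps the full Raman arm — preprocessing, PCA,
rank-sum score tests, cell-grouped LDA and the repeated-subsampling
misclassification estimate — and ``SersQuantifier`` wraps the SERS arm —
per-map noise thresholds, dual-band bright-pixel counting and relative
expression versus a reference condition.  Each model is constructed from
data, ``fit()`` returns a results object carrying estimates and diagnostics,
and ``summary()`` renders a plain-text report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import chemometrics as chem
from . import sersquant as sq
from .containers import HyperspectralMap, LabeledSpectraSet
from .preprocess import PreprocessConfig, preprocess_pipeline

__all__ = [
    "RamanCellClassifier",
    "RamanClassificationResults",
    "SersQuantifier",
    "SersQuantResults",
]


def _child_seeds(seed, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


@dataclass
class RamanClassificationResults:
    """Estimates and diagnostics of the fitted Raman classification model."""

    pca: chem.PCAModel
    cumulative_variance_4: float
    score_tests: Mapping[int, pd.DataFrame]
    lda: chem.LDAModel
    holdout_accuracy: float
    confusion: pd.DataFrame
    misclassification: chem.MisclassificationResult
    n_train: int
    n_test: int

    def summary(self) -> str:
        m = self.misclassification
        lines = [
            "Raman cell-line classification",
            "=" * 46,
            f"spectra (train/test)     {self.n_train:>5d} / {self.n_test}",
            f"classes                  {', '.join(self.lda.classes)}",
            f"PC1-4 cumulative var.    {100 * self.cumulative_variance_4:6.2f} %",
            f"held-out LDA accuracy    {100 * self.holdout_accuracy:6.2f} %",
            f"mean misclassification   {100 * m.mean_error:6.3f} % "
            f"({m.n_iterations} iterations, "
            f"{m.test_spectra_per_class} test spectra/class)",
            "",
            "confusion matrix (held-out half, rows = true):",
            self.confusion.to_string(),
        ]
        for k, table in self.score_tests.items():
            lines.append("")
            lines.append(f"Wilcoxon rank-sum on PC{k} scores:")
            lines.append(table[["group_a", "group_b", "pvalue",
                                "pvalue_holm", "stars"]].to_string(index=False))
        return "\n".join(lines)


class RamanCellClassifier:
    """PCA/LDA classification model for a labeled single-cell Raman dataset.

    Parameters
    ----------
    data : LabeledSpectraSet
        Raw (unpreprocessed) labeled spectra, e.g. from
        :func:`sersraman.synthetic.simulate_raman_dataset`.
    preprocess : PreprocessConfig, optional
        Preprocessing settings.  PCA runs on the native-resolution branch,
        the LDA on the rebinned branch (``rebin_width`` cm^-1).
    """

    def __init__(self, data: LabeledSpectraSet,
                 preprocess: PreprocessConfig | None = None) -> None:
        data.require_labels()
        self.data = data
        self.preprocess = preprocess or PreprocessConfig()

    @classmethod
    def from_dataframe(cls, spectra: pd.DataFrame, labels: pd.DataFrame,
                       **kwargs) -> "RamanCellClassifier":
        """Build from a wide spectra table (``wavenumber_cm1`` + one column
        per spectrum) and a label table (``spectrum, cell_id, class_label``)."""
        from .containers import SpectralAxis
        w = spectra["wavenumber_cm1"].to_numpy(float)
        names = [c for c in spectra.columns if c != "wavenumber_cm1"]
        X = spectra[names].to_numpy(float).T
        lab = labels.set_index("spectrum").loc[names]
        sset = LabeledSpectraSet(SpectralAxis(w), X,
                                 lab["class_label"].to_numpy(object),
                                 lab["cell_id"].to_numpy(object))
        return cls(sset, **kwargs)

    def fit(self, train_fraction: float = 0.5, n_iterations: int = 1000,
            n_score_pcs: int = 4, seed=None) -> RamanClassificationResults:
        """Run the full analysis; ``seed`` drives the split and the repeated
        test draws (one root seed, child streams per stage)."""
        s_split, s_iter = _child_seeds(seed, 2)
        native = preprocess_pipeline(self.data, self.preprocess)
        rebinned = preprocess_pipeline(self.data, self.preprocess.for_lda())

        pca = chem.pca_svd(native)
        cum4 = chem.cumulative_variance(pca, min(4, pca.n_components))
        labels = native.require_labels()
        tests = {k + 1: chem.wilcoxon_scores(pca.scores[:, k], labels)
                 for k in range(min(n_score_pcs, pca.n_components))}

        train, test = chem.grouped_split(rebinned, train_fraction, s_split)
        lda = chem.lda_fit(train)
        pred = lda.predict(test.intensities)
        truth = test.require_labels().astype(str)
        acc = float(np.mean(pred == truth))
        confusion = pd.crosstab(pd.Series(truth, name="true"),
                                pd.Series(pred, name="predicted"),
                                dropna=False)
        mis = chem.misclassification_estimate(rebinned, n_iterations,
                                              rng_seed=s_iter)
        return RamanClassificationResults(
            pca=pca, cumulative_variance_4=cum4, score_tests=tests, lda=lda,
            holdout_accuracy=acc, confusion=confusion, misclassification=mis,
            n_train=train.n_spectra, n_test=test.n_spectra)


# ---------------------------------------------------------------------------
# SERS arm
# ---------------------------------------------------------------------------

@dataclass
class SersQuantResults:
    """Per-condition bright-pixel counts and relative expression."""

    per_condition: Mapping[str, sq.QuantResult]
    reference: str
    relative: Mapping[str, sq.RelativeExpression]

    def summary(self) -> str:
        lines = ["SERS bright-pixel quantification",
                 "=" * 56,
                 f"{'condition':<20}{'maps':>5}{'total px':>10}"
                 f"{'mean/cell':>11}{'rel %':>9}"]
        for name, qr in self.per_condition.items():
            rel = self.relative[name].percent
            lines.append(f"{name:<20}{qr.n_maps:>5d}{qr.total_count:>10d}"
                         f"{qr.mean_count:>11.1f}{rel:>9.1f}")
        lines.append(f"reference condition: {self.reference}")
        for name, rel in self.relative.items():
            if name != self.reference:
                lines.append(f"{name}: {rel.percent:.1f} % of reference "
                             f"({rel.reduction_percent:.1f} % reduction)")
        return "\n".join(lines)


class SersQuantifier:
    """Dual-band threshold quantification model over SERS map conditions.

    Parameters
    ----------
    conditions : mapping of condition name -> list of HyperspectralMap
    reference : name of the condition all others are expressed relative to
    """

    def __init__(self, conditions: Mapping[str, Sequence[HyperspectralMap]],
                 reference: str,
                 reporter_centers: Sequence[float] = sq.DEFAULT_REPORTER_CENTERS,
                 reporter_halfwidth: float = sq.DEFAULT_REPORTER_HALFWIDTH,
                 noise_window: tuple[float, float] = sq.DEFAULT_NOISE_WINDOW,
                 ) -> None:
        if reference not in conditions:
            raise ValueError(f"reference condition {reference!r} not present")
        self.conditions = dict(conditions)
        self.reference = reference
        self.reporter_centers = tuple(reporter_centers)
        self.reporter_halfwidth = reporter_halfwidth
        self.noise_window = noise_window

    def fit(self) -> SersQuantResults:
        per = {name: sq.quantify_condition(maps, self.reporter_centers,
                                           self.reporter_halfwidth,
                                           self.noise_window)
               for name, maps in self.conditions.items()}
        ref = per[self.reference]
        relative = {name: sq.relative_expression(qr, ref)
                    for name, qr in per.items()}
        return SersQuantResults(per_condition=per, reference=self.reference,
                                relative=relative)
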