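"""Sample classification from selected features, and per-feature t-tests.

The discrimination experiment asks whether the features chosen by the
tensor pipeline separate precancerous (treated) from normal (control)
samples.  The feature matrix concatenates the selected liver-miRNA,
serum-miRNA and liver-mRNA rows, z-scored per feature, and a linear
discriminant is evaluated by leave-one-out cross-validation (each sample
predicted by a model trained on the other seventeen).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestCentroid

from .io import ExpressionBundle, ExpressionMatrix, SampleDesign

logger = logging.getLogger(__name__)

CLASSIFIERS = ("lda", "lda_shrinkage", "logistic", "nearest_centroid")
#: confusion-matrix row/column order
CLASS_ORDER = ("control", "treated")


@dataclass
class ClassificationReport:
    """LOOCV (or in-sample) confusion matrix and accuracy."""

    confusion: np.ndarray  # 2x2, rows = true class, columns = predicted
    accuracy: float
    method: str
    scheme: str
    classes: tuple[str, str] = CLASS_ORDER

    def to_frame(self) -> pd.DataFrame:
        idx = [f"true_{c}" for c in self.classes]
        cols = [f"pred_{c}" for c in self.classes]
        return pd.DataFrame(self.confusion, index=idx, columns=cols)

    def summary(self) -> str:
        lines = [f"{self.scheme} classification ({self.method}): "
                 f"accuracy {self.accuracy:.1%}", str(self.to_frame())]
        return "\n".join(lines)


@dataclass
class DifferentialResult:
    """Per-feature two-sample comparison."""

    feature_id: str
    mean_treated: float
    mean_control: float
    t_statistic: float
    p_value: float
    significant: bool


def _make_classifier(method: str):
    if method == "lda":
        # SVD solver copes with singular within-class covariance
        return LinearDiscriminantAnalysis(solver="svd")
    if method == "lda_shrinkage":
        # explicit regularised (diagonal-loaded) covariance
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if method == "logistic":
        return LogisticRegression(max_iter=1000)
    if method == "nearest_centroid":
        return NearestCentroid()
    raise ValueError(f"unknown classifier {method!r}; expected one of {CLASSIFIERS}")


def feature_matrix(
    bundle: ExpressionBundle,
    selected_mrna: list[str],
    selected_mirna: list[str],
) -> np.ndarray:
    """Samples x features matrix of the selected rows, z-scored per feature.

    miRNA identifiers index both the liver and the serum matrix (the same
    marker set is profiled in both compartments).
    """
    blocks = []
    for matrix, ids in (
        (bundle.mirna_liver, selected_mirna),
        (bundle.mirna_serum, selected_mirna),
        (bundle.mrna_liver, selected_mrna),
    ):
        if not ids:
            continue
        pos = {f: i for i, f in enumerate(matrix.feature_ids)}
        missing = [f for f in ids if f not in pos]
        if missing:
            raise ValueError(f"{matrix.modality}: unknown feature ids {missing[:5]}")
        rows = matrix.values[[pos[f] for f in ids], :]
        sd = rows.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        blocks.append((rows - rows.mean(axis=1, keepdims=True)) / sd)
    if not blocks:
        raise ValueError("no features selected for classification")
    return np.vstack(blocks).T


def loocv_classify(
    bundle: ExpressionBundle,
    selected_mrna: list[str],
    selected_mirna: list[str],
    method: str = "lda",
    scheme: str = "loocv",
) -> ClassificationReport:
    """Classify samples from the selected features.

    ``scheme='loocv'`` (default) refits the classifier with each sample
    held out; ``scheme='insample'`` fits once on everything and predicts
    the training samples.
    """
    if scheme not in ("loocv", "insample"):
        raise ValueError("scheme must be 'loocv' or 'insample'")
    x = feature_matrix(bundle, selected_mrna, selected_mirna)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 selected features")
    y = np.asarray(bundle.design.group)
    for cls in CLASS_ORDER:
        if (y == cls).sum() < 3:
            raise ValueError(f"need at least 3 samples per group, {cls} has {(y == cls).sum()}")
    n = x.shape[0]
    pred = np.empty(n, dtype=object)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinearity warnings on tiny folds
        if scheme == "insample":
            clf = _make_classifier(method).fit(x, y)
            pred[:] = clf.predict(x)
        else:
            for j in range(n):
                mask = np.ones(n, dtype=bool)
                mask[j] = False
                clf = _make_classifier(method).fit(x[mask], y[mask])
                pred[j] = clf.predict(x[j][None, :])[0]
    confusion = np.zeros((2, 2), dtype=int)
    for true, hat in zip(y, pred):
        confusion[CLASS_ORDER.index(true), CLASS_ORDER.index(hat)] += 1
    accuracy = float(np.trace(confusion)) / n
    logger.info("%s %s accuracy: %.1f%%", scheme, method, 100 * accuracy)
    return ClassificationReport(confusion, accuracy, method, scheme)


def group_t_tests(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    alpha: float = 0.05,
    welch: bool = False,
) -> list[DifferentialResult]:
    """Student two-sample t-test (two-sided) for every feature.

    Equal-variance by default; ``welch=True`` drops the pooled-variance
    assumption.  Features constant in both groups get P = 1 by convention.
    """
    treated = design.group_mask
    if treated.sum() < 2 or (~treated).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    a = matrix.values[:, treated]
    b = matrix.values[:, ~treated]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    degenerate = np.isnan(p)
    if degenerate.any():
        warnings.warn(f"{degenerate.sum()} feature(s) constant in both groups; P set to 1")
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return [
        DifferentialResult(
            feature_id=f,
            mean_treated=float(a[i].mean()),
            mean_control=float(b[i].mean()),
            t_statistic=float(t[i]),
            p_value=float(p[i]),
            significant=bool(p[i] < alpha),
        )
        for i, f in enumerate(matrix.feature_ids)
    ]


def differential_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
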