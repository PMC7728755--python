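"""The statsmodels-style front door: a model object fitted to a bundle.

:class:`TensorFeatureModel` holds an :class:`~tensorfe.io.ExpressionBundle`
plus the analysis settings; :meth:`TensorFeatureModel.fit` executes the
whole chain — preprocessing, outer-product tensor, HOSVD, component
association, chi-square / BH feature selection and LOOCV classification —
and returns a :class:`TensorFeatureResults` carrying every intermediate
object, the selected identifiers and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from .components import (
    ComponentSelection,
    associate_sample_components,
    select_feature_components,
)
from .hosvd import HOSVDResult, hosvd, hosvd_product
from .io import ExpressionBundle, read_bundle
from .scoring import FeatureScores, bh_adjust, chi2_scores, select_features
from .tensor import build_tensor, preprocess

logger = logging.getLogger(__name__)

#: tensors at most this many entries are decomposed densely
DENSE_LIMIT = 2_000_000


class TensorFeatureModel:
    """Tensor-decomposition unsupervised feature extraction on one bundle.

    Parameters
    ----------
    bundle : aligned three-matrix expression bundle
    preprocess : per-matrix transform applied before the tensor product
        (default ``center_sample``; see :func:`tensorfe.tensor.preprocess`)
    alpha : significance level for sample-component association
    rule, k, energy_fraction, scale_dominance :
        feature-component selection, see
        :func:`tensorfe.components.select_feature_components`
    threshold : BH-adjusted P cut-off for feature selection
    pooled_bh : correct mRNA and miRNA P-values as one family instead of
        per modality
    classifier, scheme : see :func:`tensorfe.classify.loocv_classify`
    manual_l2 : explicit sample-component indices overriding the automatic
        association (the literal published choice would be ``[1, 2, 3]``
        in zero-based indexing)
    """

    def __init__(
        self,
        bundle: ExpressionBundle,
        preprocess: str = "center_sample",
        alpha: float = 0.05,
        rule: str = "energy",
        k: int = 4,
        energy_fraction: float = 0.8,
        scale_dominance: float | None = 3.0,
        threshold: float = 0.01,
        pooled_bh: bool = False,
        center_chi2: bool = False,
        classifier: str = "lda",
        scheme: str = "loocv",
        manual_l2: list[int] | None = None,
    ):
        if not 0 < threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        self.bundle = bundle
        self.preprocess_method = preprocess
        self.alpha = alpha
        self.rule = rule
        self.k = k
        self.energy_fraction = energy_fraction
        self.scale_dominance = scale_dominance
        self.threshold = threshold
        self.pooled_bh = pooled_bh
        self.center_chi2 = center_chi2
        self.classifier = classifier
        self.scheme = scheme
        self.manual_l2 = manual_l2

    @classmethod
    def from_directory(cls, directory: str | Path, **kwargs) -> "TensorFeatureModel":
        """Build the model from a five-file TSV bundle directory."""
        return cls(read_bundle(directory), **kwargs)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "TensorFeatureResults":
        b = self.bundle
        logger.info("preprocess: %s", self.preprocess_method)
        mats = [preprocess(m, self.preprocess_method) for m in b.matrices]

        n, m_, k_ = mats[0].n_features, mats[0].n_samples, mats[1].n_features
        dense = n * m_ * k_ * 2 <= DENSE_LIMIT
        tensor = build_tensor(*mats, dense=dense)
        logger.info("tensor %s (%s)", tensor.shape, "dense" if dense else "structured")
        decomposition = hosvd(tensor) if dense else hosvd_product(tensor)

        sample_assoc = associate_sample_components(
            decomposition.factor(2), b.design, alpha=self.alpha
        )
        if self.manual_l2 is not None:
            for c in sample_assoc:
                if c.index in self.manual_l2 and c.kind not in ("group", "time"):
                    c.kind = "group" if c.p_group <= c.p_time else "time"
                elif c.index not in self.manual_l2 and c.kind in ("group", "time"):
                    c.kind = "none"
        selection = select_feature_components(
            decomposition,
            sample_assoc,
            rule=self.rule,
            k=self.k,
            energy_fraction=self.energy_fraction,
            scale_dominance=self.scale_dominance,
        )

        mrna_scores = chi2_scores(
            decomposition.factor(1), selection.mrna_components,
            feature_ids=mats[0].feature_ids, threshold=self.threshold,
            center=self.center_chi2,
        )
        mirna_scores = chi2_scores(
            decomposition.factor(3), selection.mirna_components,
            feature_ids=mats[1].feature_ids, threshold=self.threshold,
            center=self.center_chi2,
        )
        if self.pooled_bh:
            pooled = bh_adjust(np.concatenate([mrna_scores.p_raw, mirna_scores.p_raw]))
            mrna_scores.p_adjusted = pooled[: len(mrna_scores.p_raw)]
            mirna_scores.p_adjusted = pooled[len(mrna_scores.p_raw):]

        selected_mrna = select_features(mrna_scores)
        selected_mirna = select_features(mirna_scores)
        logger.info("selected %d mRNAs, %d miRNAs (BH < %g)",
                    len(selected_mrna), len(selected_mirna), self.threshold)

        classification = None
        if len(selected_mrna) + len(selected_mirna) >= 2:
            classification = _classify.loocv_classify(
                b, selected_mrna, selected_mirna,
                method=self.classifier, scheme=self.scheme,
            )
        else:
            logger.warning("fewer than 2 features selected; classification skipped")

        return TensorFeatureResults(
            model=self,
            decomposition=decomposition,
            selection=selection,
            mrna_scores=mrna_scores,
            mirna_scores=mirna_scores,
            selected_mrna=selected_mrna,
            selected_mirna=selected_mirna,
            classification=classification,
        )


@dataclass
class TensorFeatureResults:
    """Everything the fitted pipeline produced."""

    model: TensorFeatureModel
    decomposition: HOSVDResult
    selection: ComponentSelection
    mrna_scores: FeatureScores
    mirna_scores: FeatureScores
    selected_mrna: list[str]
    selected_mirna: list[str]
    classification: _classify.ClassificationReport | None
    _extra: dict = field(default_factory=dict)

    # -- reporting ---------------------------------------------------------

    def component_table(self) -> pd.DataFrame:
        rows = [
            {"l2": c.index, "kind": c.kind, "p_group": c.p_group, "p_time": c.p_time}
            for c in self.selection.sample_components
        ]
        return pd.DataFrame(rows)

    def recovery(self) -> dict | None:
        """Compare selections against planted truth, if the bundle has one."""
        truth = self.model.bundle.truth
        if truth is None:
            return None
        out = {}
        for kind, sel in (("mrna", self.selected_mrna), ("mirna", self.selected_mirna)):
            true = set(truth.get(kind, []))
            got = set(sel)
            out[kind] = {
                "n_selected": len(got),
                "n_true": len(true),
                "false_positive": len(got - true),
                "false_negative": len(true - got),
                "exact": got == true,
            }
        return out

    def summary(self) -> str:
        m = self.model
        b = m.bundle
        lines = [
            "Tensor-decomposition unsupervised feature extraction",
            "====================================================",
            f"samples: {b.design.n_samples} "
            f"({int(b.design.group_mask.sum())} treated / "
            f"{int((~b.design.group_mask).sum())} control, "
            f"timepoints {b.design.timepoint_order})",
            f"features: {b.mrna_liver.n_features} mRNA, "
            f"{b.mirna_liver.n_features} miRNA (liver + serum)",
            f"preprocess: {m.preprocess_method}; component rule: {m.rule}; "
            f"BH threshold: {m.threshold}",
            "",
            f"sample components (l2): "
            f"{[c.index for c in self.selection.sample_components if c.kind == 'group']} group, "
            f"{[c.index for c in self.selection.sample_components if c.kind == 'time']} time",
            f"feature components: l1={[int(i) for i in self.selection.mrna_components]} "
            f"l3={[int(i) for i in self.selection.mirna_components]}",
            f"selected features: {len(self.selected_mrna)} mRNAs, "
            f"{len(self.selected_mirna)} miRNAs",
        ]
        rec = self.recovery()
        if rec is not None:
            for kind in ("mrna", "mirna"):
                r = rec[kind]
                lines.append(
                    f"  {kind}: {r['n_selected']} selected vs {r['n_true']} planted "
                    f"(FP {r['false_positive']}, FN {r['false_negative']})"
                )
        if self.classification is not None:
            lines += ["", self.classification.summary()]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def to_directory(self, directory: str | Path) -> list[Path]:
        """Write result tables (TSV) into a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name, frame in (
            ("mrna_scores", self.mrna_scores.to_frame()),
            ("mirna_scores", self.mirna_scores.to_frame()),
            ("components", self.component_table()),
        ):
            path = directory / f"{name}.tsv"
            frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
            written.append(path)
        if self.classification is not None:
            path = directory / "confusion.tsv"
            self.classification.to_frame().to_csv(path, sep="\t")
            written.append(path)
        path = directory / "summary.txt"
        path.write_text(self.summary() + "\n")
        written.append(path)
        return written
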