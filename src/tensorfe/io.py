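"""Reading and writing of expression matrices, sample designs and bundles.

All on-disk formats are plain tab-delimited text:

* expression matrix — header row of sample identifiers, first column of
  feature identifiers, one row per feature (the common GEO series-matrix
  orientation);
* sample design — columns ``sample_id``, ``group``, ``timepoint``.

Values are log-scale expression; missing values are rejected rather than
imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MODALITIES = ("mrna_liver", "mirna_liver", "mirna_serum")
GROUP_LABELS = ("treated", "control")


class BundleError(ValueError):
    """Raised when matrices and design cannot be assembled consistently."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """A features x samples grid of log-scale expression values.

    Parameters
    ----------
    values : ndarray of shape (n_features, n_samples)
    feature_ids, sample_ids : unique string identifiers for rows / columns
    modality : one of ``mrna_liver``, ``mirna_liver``, ``mirna_serum``
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    modality: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-dimensional")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.sample_ids, "sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no NaN/inf)")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, modality: str) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns), modality)

    def reorder_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy with columns permuted into the given sample order."""
        if set(sample_ids) != set(self.sample_ids) or len(sample_ids) != len(self.sample_ids):
            missing = set(sample_ids) ^ set(self.sample_ids)
            raise BundleError(f"sample-id mismatch, symmetric difference: {sorted(missing)}")
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        order = [pos[s] for s in sample_ids]
        return ExpressionMatrix(
            self.values[:, order], list(self.feature_ids), list(sample_ids), self.modality
        )


@dataclass
class SampleDesign:
    """Group and timepoint labels aligned to an ordered sample axis."""

    sample_ids: list[str]
    group: list[str]
    timepoint: list[str]
    timepoint_order: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.group = [str(g) for g in self.group]
        self.timepoint = [str(t) for t in self.timepoint]
        if not (len(self.sample_ids) == len(self.group) == len(self.timepoint)):
            raise ValueError("sample_ids, group and timepoint must have equal length")
        _check_unique(self.sample_ids, "sample ids")
        bad = sorted(set(self.group) - set(GROUP_LABELS))
        if bad:
            raise ValueError(f"unknown group labels {bad}; expected {GROUP_LABELS}")
        counts = pd.Series(self.group).value_counts()
        if len(counts) < 2 or counts.min() < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.timepoint_order is None:
            # preserve order of first appearance (e.g. 6W < 10W < 12W)
            self.timepoint_order = list(dict.fromkeys(self.timepoint))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def group_mask(self) -> np.ndarray:
        """Boolean mask, True for treated samples."""
        return np.array([g == "treated" for g in self.group])

    @property
    def timepoint_index(self) -> np.ndarray:
        """Integer codes following ``timepoint_order``."""
        pos = {t: i for i, t in enumerate(self.timepoint_order)}
        return np.array([pos[t] for t in self.timepoint])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "group": self.group, "timepoint": self.timepoint}
        )


@dataclass
class ExpressionBundle:
    """The three expression matrices sharing one sample axis, plus the design.

    ``truth`` optionally records planted signal features of a synthetic
    dataset as ``{"mrna": [...], "mirna": [...]}``.
    """

    mrna_liver: ExpressionMatrix
    mirna_liver: ExpressionMatrix
    mirna_serum: ExpressionMatrix
    design: SampleDesign
    truth: dict | None = None

    def __post_init__(self) -> None:
        sids = self.design.sample_ids
        for m in (self.mrna_liver, self.mirna_liver, self.mirna_serum):
            if m.sample_ids != sids:
                raise BundleError(
                    f"{m.modality} sample axis differs from design "
                    f"(use align_bundle to reorder)"
                )
        if self.mirna_liver.feature_ids != self.mirna_serum.feature_ids:
            raise BundleError("liver and serum miRNA matrices must share feature identifiers")
        if self.truth is not None:
            if not set(self.truth.get("mrna", [])) <= set(self.mrna_liver.feature_ids):
                raise BundleError("truth mRNA ids are not a subset of mRNA features")
            if not set(self.truth.get("mirna", [])) <= set(self.mirna_liver.feature_ids):
                raise BundleError("truth miRNA ids are not a subset of miRNA features")

    @property
    def matrices(self) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix]:
        return self.mrna_liver, self.mirna_liver, self.mirna_serum


def read_expression_matrix(path: str | Path, modality: str) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample ids, column 1 = feature ids)."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"expression matrix not found: {path}")
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        raise ValueError(f"{path}: duplicate feature ids")
    if frame.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric expression values ({exc})") from exc
    if np.isnan(values).any():
        raise ValueError(f"{path}: missing values are not supported")
    return ExpressionMatrix(values, list(frame.index.astype(str)),
                            list(frame.columns.astype(str)), modality)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t", float_format="%.10g")


def read_design(path: str | Path) -> SampleDesign:
    """Read a TSV design table with columns sample_id, group, timepoint."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"design table not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "timepoint"}
    if not required <= set(frame.columns):
        raise ValueError(f"{path}: design needs columns {sorted(required)}")
    return SampleDesign(list(frame["sample_id"]), list(frame["group"]), list(frame["timepoint"]))


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def align_bundle(
    mrna_liver: ExpressionMatrix,
    mirna_liver: ExpressionMatrix,
    mirna_serum: ExpressionMatrix,
    design: SampleDesign,
    truth: dict | None = None,
) -> ExpressionBundle:
    """Reorder all matrices into the design's sample order (a pure permutation)."""
    aligned = [m.reorder_samples(design.sample_ids) for m in (mrna_liver, mirna_liver, mirna_serum)]
    return ExpressionBundle(*aligned, design=design, truth=truth)


def read_bundle(directory: str | Path) -> ExpressionBundle:
    """Read the five-file bundle layout produced by ``write_bundle``."""
    directory = Path(directory)
    mats = [read_expression_matrix(directory / f"{m}.tsv", m) for m in MODALITIES]
    design = read_design(directory / "design.tsv")
    truth = None
    truth_path = directory / "truth.tsv"
    if truth_path.is_file():
        tf = pd.read_csv(truth_path, sep="\t", dtype=str)
        truth = {
            "mrna": list(tf.loc[tf["kind"] == "mrna", "feature_id"]),
            "mirna": list(tf.loc[tf["kind"] == "mirna", "feature_id"]),
        }
    return align_bundle(*mats, design=design, truth=truth)
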