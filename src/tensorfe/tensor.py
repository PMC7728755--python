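"""Construction of the 4-way omics tensor from three expression matrices.

Given the liver mRNA matrix ``b`` (N x M), the liver miRNA matrix ``a1``
(K x M) and the serum-exosome miRNA matrix ``a2`` (K x M), the tensor
``x`` of shape N x M x K x 2 is the per-sample outer product

    x[i, j, k, 0] = a1[k, j] * b[i, j]        (liver platform slice)
    x[i, j, k, 1] = a2[k, j] * b[i, j]        (serum platform slice)

Because every sample's slice is a rank-one outer product, the mode Gram
matrices needed for HOSVD can be computed without materialising the dense
array; :class:`ProductTensor` carries that structured form.  Correctness is
defined by the dense semantics of :func:`build_tensor`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

PLATFORMS = ("liver", "serum")

#: Preprocessing methods accepted by :func:`preprocess`.
PREPROCESS_METHODS = ("none", "log2p1", "zscore_feature", "center_sample")


def preprocess(matrix: ExpressionMatrix, method: str = "none") -> ExpressionMatrix:
    """Transform an expression matrix prior to tensor construction.

    ``none``
        identity; reproduces the literal product formulas.
    ``log2p1``
        log2(1 + x), for raw count/intensity inputs.
    ``zscore_feature``
        centre and scale each feature (row) to mean 0, SD 1; constant rows
        are dropped with a warning.
    ``center_sample``
        subtract each sample's mean across features (column centring).
        This removes the grand expression-scale direction from the feature
        modes while keeping the across-feature profile that propagates
        sample contrasts through the rank-one products — the default of the
        analysis pipeline.
    """
    if method not in PREPROCESS_METHODS:
        raise ValueError(f"unknown preprocess method {method!r}; expected one of {PREPROCESS_METHODS}")
    v = matrix.values
    if method == "none":
        return matrix
    if method == "log2p1":
        out = np.log2(1.0 + v)
        return ExpressionMatrix(out, list(matrix.feature_ids), list(matrix.sample_ids), matrix.modality)
    if method == "center_sample":
        out = v - v.mean(axis=0, keepdims=True)
        return ExpressionMatrix(out, list(matrix.feature_ids), list(matrix.sample_ids), matrix.modality)
    # zscore_feature
    sd = v.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [f for f, k in zip(matrix.feature_ids, keep) if not k]
        logger.warning("zscore_feature: dropping %d constant features (%s...)",
                       len(dropped), dropped[:3])
    v = v[keep]
    out = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, keepdims=True)
    ids = [f for f, k in zip(matrix.feature_ids, keep) if k]
    return ExpressionMatrix(out, ids, list(matrix.sample_ids), matrix.modality)


def _check_sample_axis(*matrices: ExpressionMatrix) -> list[str]:
    sids = matrices[0].sample_ids
    for m in matrices[1:]:
        if m.sample_ids != sids:
            raise ValueError(
                "sample axes differ between matrices; align the bundle first "
                f"({matrices[0].modality} vs {m.modality})"
            )
    return list(sids)


@dataclass
class OmicsTensor:
    """Dense 4-way array x[i, j, k, m] with identifier axes."""

    values: np.ndarray  # N x M x K x 2
    mrna_ids: list[str]
    sample_ids: list[str]
    mirna_ids: list[str]
    platforms: tuple[str, str] = PLATFORMS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.mrna_ids), len(self.sample_ids), len(self.mirna_ids), 2)
        if self.values.shape != expected:
            raise ValueError(f"tensor shape {self.values.shape} != axis ids {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tensor values must be finite")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.values.shape

    def frobenius_norm(self) -> float:
        return float(np.linalg.norm(self.values))


class ProductTensor:
    """The same tensor in structured (non-materialised) form.

    Stores the three factor matrices and exposes the mode Gram matrices

        G1[i,i'] = sum_jkm x[i,j,k,m] x[i',j,k,m] = (B W B^T),  W = diag(w_j)
        G2[j,j'] = (B^T B) o (A1^T A1 + A2^T A2)      (Hadamard product)
        G3[k,k'] = sum_m A_m S A_m^T,                 S = diag(|B col j|^2)
        G4[m,m'] = sum_j s_j (A_m^T A_m')_{jj}

    with w_j = sum_km a_m[k,j]^2 and s_j = sum_i b[i,j]^2, which is all the
    HOSVD factor computation needs.
    """

    def __init__(self, mrna: np.ndarray, mirna_liver: np.ndarray, mirna_serum: np.ndarray,
                 mrna_ids: list[str], sample_ids: list[str], mirna_ids: list[str]):
        self.b = np.asarray(mrna, dtype=float)
        self.a = (np.asarray(mirna_liver, dtype=float), np.asarray(mirna_serum, dtype=float))
        if self.b.shape[1] != self.a[0].shape[1] or self.a[0].shape != self.a[1].shape:
            raise ValueError("factor matrices disagree on the sample axis")
        self.mrna_ids = list(mrna_ids)
        self.sample_ids = list(sample_ids)
        self.mirna_ids = list(mirna_ids)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return (self.b.shape[0], self.b.shape[1], self.a[0].shape[0], 2)

    def mode_gram(self, mode: int) -> np.ndarray:
        if mode == 1:
            w = (self.a[0] ** 2).sum(axis=0) + (self.a[1] ** 2).sum(axis=0)
            return (self.b * w) @ self.b.T
        if mode == 2:
            return (self.b.T @ self.b) * (self.a[0].T @ self.a[0] + self.a[1].T @ self.a[1])
        if mode == 3:
            s = (self.b ** 2).sum(axis=0)
            return (self.a[0] * s) @ self.a[0].T + (self.a[1] * s) @ self.a[1].T
        if mode == 4:
            s = (self.b ** 2).sum(axis=0)
            g = np.empty((2, 2))
            for m in range(2):
                for mp in range(m, 2):
                    g[m, mp] = g[mp, m] = float((s * (self.a[m] * self.a[mp]).sum(axis=0)).sum())
            return g
        raise ValueError(f"mode must be 1..4, got {mode}")

    def frobenius_norm(self) -> float:
        return float(np.sqrt(np.trace(self.mode_gram(4))))

    def to_dense(self) -> OmicsTensor:
        values = np.stack(
            [np.einsum("kj,ij->ijk", am, self.b) for am in self.a], axis=-1
        )
        return OmicsTensor(values, self.mrna_ids, self.sample_ids, self.mirna_ids)


def build_tensor(
    mrna_liver: ExpressionMatrix,
    mirna_liver: ExpressionMatrix,
    mirna_serum: ExpressionMatrix,
    dense: bool = True,
) -> OmicsTensor | ProductTensor:
    """Form the outer-product tensor from the three (aligned) matrices.

    With ``dense=False`` the structured :class:`ProductTensor` is returned
    instead of materialising the N x M x K x 2 array; both represent the
    identical tensor.
    """
    sids = _check_sample_axis(mrna_liver, mirna_liver, mirna_serum)
    if mirna_liver.feature_ids != mirna_serum.feature_ids:
        raise ValueError("liver and serum miRNA matrices must share feature identifiers")
    pt = ProductTensor(
        mrna_liver.values, mirna_liver.values, mirna_serum.values,
        mrna_liver.feature_ids, sids, mirna_liver.feature_ids,
    )
    return pt.to_dense() if dense else pt
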