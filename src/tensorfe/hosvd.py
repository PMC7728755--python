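"""Higher-order singular value decomposition of the 4-way omics tensor.

The full (non-truncated) HOSVD expands the tensor as

    x[i,j,k,m] = sum_{l1,l2,l3,l4} G[l1,l2,l3,l4]
                 u1[i,l1] u2[j,l2] u3[k,l3] u4[m,l4]

where each ``u`` is the orthogonal matrix of left singular vectors of the
corresponding mode unfolding and the core ``G`` is the tensor contracted
with all factor transposes.  Factors are computed from the mode Gram
matrices (unfolding times its transpose): the Gram has the size of the mode
dimension, which here (N, M, K, 2) is always far smaller than the product
of the remaining dimensions, and the eigenbasis is automatically a complete
orthonormal basis even when the unfolding is rank-deficient.

Sign convention: the largest-magnitude entry of every factor column is made
positive (first such entry on ties), so output is reproducible despite the
inherent sign ambiguity of singular vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensor import OmicsTensor, ProductTensor

N_MODES = 4

#: relative tolerance used by internal orthogonality / consistency checks
TOL = 1e-8


def unfold(values: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n matricisation of a 4-way array.

    Rows are indexed by the chosen mode; columns enumerate the remaining
    modes in their original order, last axis varying fastest (C order), so
    ``fold(unfold(x, n), n, x.shape) == x``.
    """
    values = np.asarray(values)
    if values.ndim != N_MODES:
        raise ValueError(f"expected a 4-way array, got {values.ndim} modes")
    if not 1 <= mode <= N_MODES:
        raise ValueError(f"mode must be in 1..{N_MODES}, got {mode}")
    return np.moveaxis(values, mode - 1, 0).reshape(values.shape[mode - 1], -1)


def fold(matrix: np.ndarray, mode: int, shape: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`unfold` for the given original shape."""
    if not 1 <= mode <= N_MODES:
        raise ValueError(f"mode must be in 1..{N_MODES}, got {mode}")
    rest = [s for i, s in enumerate(shape) if i != mode - 1]
    return np.moveaxis(np.asarray(matrix).reshape(shape[mode - 1], *rest), 0, mode - 1)


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Flip factor columns so each column's largest-|entry| is positive."""
    idx = np.abs(u).argmax(axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs


def _factor_from_gram(gram: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose a mode Gram matrix into (factor, singular values)."""
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval, kind="stable")[::-1]  # ties keep input order
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    sv = np.sqrt(np.clip(eigval, 0.0, None))
    return _fix_signs(eigvec), sv


@dataclass
class HOSVDResult:
    """Factors, mode singular values and (optionally dense) core tensor.

    For the structured decomposition of a :class:`ProductTensor` the full
    core is never materialised; sub-blocks are available via
    :meth:`core_block`.
    """

    factors: list[np.ndarray]
    mode_singular_values: list[np.ndarray]
    core: np.ndarray | None = None
    shape: tuple[int, int, int, int] = None  # type: ignore[assignment]
    _source: ProductTensor | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.shape is None:
            self.shape = tuple(f.shape[0] for f in self.factors)  # type: ignore[assignment]

    def factor(self, mode: int) -> np.ndarray:
        if not 1 <= mode <= N_MODES:
            raise ValueError(f"mode must be in 1..{N_MODES}, got {mode}")
        return self.factors[mode - 1]

    def orthogonality_error(self) -> float:
        return max(
            float(np.abs(f.T @ f - np.eye(f.shape[1])).max()) for f in self.factors
        )

    def core_block(
        self,
        l1: np.ndarray | list[int] | None = None,
        l2: np.ndarray | list[int] | None = None,
        l3: np.ndarray | list[int] | None = None,
        l4: np.ndarray | list[int] | None = None,
    ) -> np.ndarray:
        """Core entries G[l1, l2, l3, l4] for the requested index sets."""
        idx = [
            np.arange(self.shape[d]) if sel is None else np.asarray(sel, dtype=int)
            for d, sel in enumerate((l1, l2, l3, l4))
        ]
        for d, sel in enumerate(idx):
            if sel.size and (sel.min() < 0 or sel.max() >= self.shape[d]):
                raise IndexError(f"component index out of range for mode {d + 1}")
        if self.core is not None:
            return self.core[np.ix_(*idx)]
        src = self._source
        if src is None:
            raise ValueError("no core available: result has neither a dense core nor a source")
        u1, u2, u3, u4 = self.factors
        p = u1[:, idx[0]].T @ src.b                      # |l1| x M
        block = []
        for m in range(2):
            q = u3[:, idx[2]].T @ src.a[m]               # |l3| x M
            block.append(np.einsum("aj,cj,jb->abc", p, q, u2[:, idx[1]]))
        stacked = np.stack(block, axis=-1)               # |l1| x |l2| x |l3| x 2
        return np.einsum("abcm,md->abcd", stacked, u4[:, idx[3]])

    def reconstruct(self) -> np.ndarray:
        """Evaluate the full expansion (dense core required)."""
        if self.core is None:
            raise ValueError("reconstruction requires the dense core")
        out = self.core
        for mode, u in enumerate(self.factors):
            if u.shape[1] != out.shape[mode]:
                raise ValueError("factor/core shape mismatch")
            out = np.tensordot(u, out, axes=(1, mode))
            out = np.moveaxis(out, 0, mode)
        return out


def hosvd(tensor: OmicsTensor | np.ndarray) -> HOSVDResult:
    """Full HOSVD of a dense 4-way tensor."""
    values = tensor.values if isinstance(tensor, OmicsTensor) else np.asarray(tensor, dtype=float)
    if values.ndim != N_MODES:
        raise ValueError("expected a 4-way tensor")
    if not np.all(np.isfinite(values)):
        raise ValueError("tensor contains non-finite values")
    factors, svs = [], []
    for mode in range(1, N_MODES + 1):
        unf = unfold(values, mode)
        u, sv = _factor_from_gram(unf @ unf.T)
        factors.append(u)
        svs.append(sv)
    core = np.einsum(
        "ijkm,ia,jb,kc,md->abcd", values, factors[0], factors[1], factors[2], factors[3],
        optimize=True,
    )
    return HOSVDResult(factors, svs, core=core, shape=values.shape)


def hosvd_product(pt: ProductTensor) -> HOSVDResult:
    """Structured HOSVD exploiting the per-sample outer-product form.

    Identical factors and singular values as :func:`hosvd` on the dense
    tensor (up to numerical round-off), but nothing of size N*M*K*2 is ever
    allocated; the core is served on demand through ``core_block``.
    """
    for arr in (pt.b, *pt.a):
        if not np.all(np.isfinite(arr)):
            raise ValueError("tensor contains non-finite values")
    factors, svs = [], []
    for mode in range(1, N_MODES + 1):
        u, sv = _factor_from_gram(pt.mode_gram(mode))
        factors.append(u)
        svs.append(sv)
    return HOSVDResult(factors, svs, core=None, shape=pt.shape, _source=pt)
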