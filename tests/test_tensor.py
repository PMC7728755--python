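"""Preprocessing and the outer-product tensor, against brute-force oracles."""

import numpy as np
import pytest

from tensorfe import ExpressionMatrix, build_tensor, preprocess
from tensorfe.tensor import ProductTensor
from tensorfe.hosvd import unfold


def _mat(values, modality, prefix):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        modality,
    )


def _random_triplet(rng, n=5, k=3, m=4):
    return (
        _mat(rng.normal(size=(n, m)), "mrna_liver", "g"),
        _mat(rng.normal(size=(k, m)), "mirna_liver", "mi"),
        _mat(rng.normal(size=(k, m)), "mirna_serum", "mi"),
    )


def brute_force_tensor(b, a1, a2):
    """Independent triple-loop oracle for the construction rule."""
    n, m = b.shape
    k = a1.shape[0]
    out = np.empty((n, m, k, 2))
    for i in range(n):
        for j in range(m):
            for kk in range(k):
                out[i, j, kk, 0] = a1[kk, j] * b[i, j]
                out[i, j, kk, 1] = a2[kk, j] * b[i, j]
    return out


class TestPreprocess:
    def test_none_is_identity(self, rng):
        m = _mat(rng.normal(size=(4, 3)), "mrna_liver", "g")
        assert preprocess(m, "none") is m

    def test_log2p1_of_seven_is_three(self):
        m = _mat([[7.0]], "mrna_liver", "g")
        assert preprocess(m, "log2p1").values[0, 0] == pytest.approx(3.0)

    def test_zscore_row_is_standardised(self):
        m = _mat([[1.0, 2.0, 3.0]], "mrna_liver", "g")
        out = preprocess(m, "zscore_feature").values[0]
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0)

    def test_zscore_drops_constant_rows_with_warning(self, caplog):
        m = _mat([[1.0, 1.0], [1.0, 2.0]], "mrna_liver", "g")
        with caplog.at_level("WARNING"):
            out = preprocess(m, "zscore_feature")
        assert out.feature_ids == ["g1"]
        assert "constant" in caplog.text

    def test_center_sample_zeroes_column_means(self, rng):
        m = _mat(rng.normal(8, 2, size=(6, 4)), "mrna_liver", "g")
        out = preprocess(m, "center_sample").values
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)

    def test_unknown_method_rejected(self, rng):
        m = _mat(rng.normal(size=(2, 2)), "mrna_liver", "g")
        with pytest.raises(ValueError, match="unknown preprocess"):
            preprocess(m, "quantile")


class TestBuildTensor:
    def test_scalar_products_example(self):
        b = _mat([[2.0, 3.0]], "mrna_liver", "g")
        a1 = _mat([[5.0, 7.0]], "mirna_liver", "mi")
        a2 = _mat([[1.0, 1.0]], "mirna_serum", "mi")
        t = build_tensor(b, a1, a2)
        np.testing.assert_allclose(t.values[0, :, 0, 0], [10.0, 21.0])
        np.testing.assert_allclose(t.values[0, :, 0, 1], [2.0, 3.0])

    def test_zero_row_gives_zero_fibers(self, rng):
        b, a1, a2 = _random_triplet(rng)
        b.values[2, :] = 0.0
        t = build_tensor(b, a1, a2)
        assert np.all(t.values[2] == 0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_exactly(self, seed):
        rng = np.random.default_rng(seed)
        b, a1, a2 = _random_triplet(rng)
        t = build_tensor(b, a1, a2)
        expected = brute_force_tensor(b.values, a1.values, a2.values)
        np.testing.assert_array_equal(t.values, expected)

    def test_bilinearity_in_mrna_and_platform_slices(self, rng):
        b, a1, a2 = _random_triplet(rng)
        base = build_tensor(b, a1, a2).values
        scaled_b = _mat(3.0 * b.values, "mrna_liver", "g")
        np.testing.assert_allclose(build_tensor(scaled_b, a1, a2).values, 3.0 * base)
        scaled_a1 = _mat(-2.0 * a1.values, "mirna_liver", "mi")
        t = build_tensor(b, scaled_a1, a2).values
        np.testing.assert_allclose(t[..., 0], -2.0 * base[..., 0])
        np.testing.assert_allclose(t[..., 1], base[..., 1])

    def test_platform_slice_norm_identity(self, rng):
        # ||slice_m||^2 = sum_j ||mRNA col j||^2 * ||miRNA_m col j||^2
        b, a1, a2 = _random_triplet(rng, n=6, k=4, m=5)
        t = build_tensor(b, a1, a2).values
        for m_idx, a in ((0, a1), (1, a2)):
            expected = float(
                ((b.values**2).sum(0) * (a.values**2).sum(0)).sum()
            )
            assert np.sum(t[..., m_idx] ** 2) == pytest.approx(expected, rel=1e-12)

    def test_sample_permutation_permutes_axis_two(self, rng):
        b, a1, a2 = _random_triplet(rng)
        perm = [2, 0, 3, 1]
        permuted = [
            ExpressionMatrix(m.values[:, perm], m.feature_ids,
                             [m.sample_ids[j] for j in perm], m.modality)
            for m in (b, a1, a2)
        ]
        t = build_tensor(b, a1, a2).values
        tp = build_tensor(*permuted).values
        np.testing.assert_array_equal(tp, t[:, perm, :, :])

    def test_sample_axis_mismatch_rejected(self, rng):
        b, a1, a2 = _random_triplet(rng)
        bad = ExpressionMatrix(a1.values, a1.feature_ids,
                               [f"x{j}" for j in range(4)], "mirna_liver")
        with pytest.raises(ValueError, match="sample axes"):
            build_tensor(b, bad, a2)


class TestProductTensor:
    def test_structured_equals_dense(self, rng):
        b, a1, a2 = _random_triplet(rng)
        pt = build_tensor(b, a1, a2, dense=False)
        assert isinstance(pt, ProductTensor)
        dense = build_tensor(b, a1, a2)
        np.testing.assert_allclose(pt.to_dense().values, dense.values, rtol=1e-12)

    @pytest.mark.parametrize("mode", [1, 2, 3, 4])
    def test_mode_grams_match_dense_unfoldings(self, rng, mode):
        b, a1, a2 = _random_triplet(rng, n=6, k=4, m=5)
        pt = build_tensor(b, a1, a2, dense=False)
        dense = pt.to_dense().values
        unf = unfold(dense, mode)
        np.testing.assert_allclose(pt.mode_gram(mode), unf @ unf.T, rtol=1e-10, atol=1e-10)

    def test_frobenius_norm_matches_dense(self, rng):
        b, a1, a2 = _random_triplet(rng)
        pt = build_tensor(b, a1, a2, dense=False)
        assert pt.frobenius_norm() == pytest.approx(
            float(np.linalg.norm(pt.to_dense().values)), rel=1e-12
        )
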