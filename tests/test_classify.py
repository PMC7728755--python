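"""LOOCV discrimination and per-feature Student t-tests."""

import numpy as np
import pytest
from scipy import stats

from tensorfe import ExpressionMatrix, SampleDesign, group_t_tests, loocv_classify
from tensorfe.io import ExpressionBundle


def _design(n_per_cell=3):
    ids, group, tp = [], [], []
    for g in ("treated", "control"):
        for w in ("6W", "10W", "12W"):
            for r in range(n_per_cell):
                ids.append(f"{g}_{w}_{r}")
                group.append(g)
                tp.append(w)
    return SampleDesign(ids, group, tp)


def _bundle_from_values(mrna, mi_liver, mi_serum, design):
    def mat(v, modality, prefix):
        return ExpressionMatrix(
            v, [f"{prefix}{i}" for i in range(v.shape[0])], design.sample_ids, modality
        )
    return ExpressionBundle(
        mat(mrna, "mrna_liver", "g"),
        mat(mi_liver, "mirna_liver", "mi"),
        mat(mi_serum, "mirna_serum", "mi"),
        design,
    )


def _separable_bundle(rng, gap=10.0):
    design = _design()
    treated = design.group_mask
    mrna = rng.normal(0, 1, (6, 18))
    mi = rng.normal(0, 1, (4, 18))
    mrna[:2, treated] += gap
    mi[:2, treated] += gap
    mi2 = mi + rng.normal(0, 0.1, mi.shape)
    return _bundle_from_values(mrna, mi, mi2, design)


class TestLoocv:
    def test_separable_groups_give_perfect_diagonal(self, rng):
        bundle = _separable_bundle(rng)
        report = loocv_classify(bundle, ["g0", "g1"], ["mi0", "mi1"])
        assert report.accuracy == 1.0
        assert np.all(np.diag(report.confusion) == [9, 9])
        assert report.confusion[0, 1] == report.confusion[1, 0] == 0

    def test_confusion_row_sums_equal_class_counts(self, rng):
        bundle = _separable_bundle(rng, gap=0.5)
        report = loocv_classify(bundle, ["g0", "g1", "g2"], ["mi0"])
        np.testing.assert_array_equal(report.confusion.sum(axis=1), [9, 9])

    def test_accuracy_invariant_to_feature_order_and_common_rescaling(self, rng):
        bundle = _separable_bundle(rng, gap=2.0)
        a = loocv_classify(bundle, ["g0", "g1"], ["mi0", "mi1"])
        b = loocv_classify(bundle, ["g1", "g0"], ["mi1", "mi0"])
        assert a.accuracy == b.accuracy
        # common affine rescale of every value
        rescaled = _bundle_from_values(
            3.0 * bundle.mrna_liver.values + 5.0,
            3.0 * bundle.mirna_liver.values + 5.0,
            3.0 * bundle.mirna_serum.values + 5.0,
            bundle.design,
        )
        c = loocv_classify(rescaled, ["g0", "g1"], ["mi0", "mi1"])
        assert c.accuracy == a.accuracy

    def test_null_data_with_permuted_labels_near_chance(self):
        # seeded permutation baseline: mean LOOCV accuracy ~ 0.5
        rng = np.random.default_rng(31)
        accs = []
        for _ in range(100):
            bundle = _separable_bundle(rng, gap=0.0)
            report = loocv_classify(bundle, ["g0", "g1", "g2"], ["mi0", "mi1"])
            accs.append(report.accuracy)
        mean = float(np.mean(accs))
        se = float(np.std(accs) / np.sqrt(len(accs)))
        assert abs(mean - 0.5) < max(3 * se, 0.1)

    def test_insample_scheme_and_alternative_classifiers(self, rng):
        bundle = _separable_bundle(rng)
        for method in ("lda_shrinkage", "logistic", "nearest_centroid"):
            report = loocv_classify(bundle, ["g0", "g1"], ["mi0"], method=method,
                                    scheme="insample")
            assert report.accuracy == 1.0
            assert report.scheme == "insample"

    def test_too_few_features_rejected(self, rng):
        bundle = _separable_bundle(rng)
        with pytest.raises(ValueError, match="at least 2"):
            loocv_classify(bundle, ["g0"], [])

    def test_unknown_feature_rejected(self, rng):
        bundle = _separable_bundle(rng)
        with pytest.raises(ValueError, match="unknown feature"):
            loocv_classify(bundle, ["g0", "nope"], ["mi0"])


class TestGroupTTests:
    def _matrix(self, rows, design):
        return ExpressionMatrix(
            np.asarray(rows, dtype=float),
            [f"g{i}" for i in range(len(rows))], design.sample_ids, "mrna_liver"
        )

    def test_identical_groups_give_t_zero_p_one(self):
        design = SampleDesign(
            ["a", "b", "c", "d", "e", "f"],
            ["treated"] * 3 + ["control"] * 3,
            ["6W", "10W", "12W"] * 2,
        )
        m = self._matrix([[1, 2, 3, 1, 2, 3]], design)
        (r,) = group_t_tests(m, design)
        assert r.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_worked_example_pooled_t(self):
        # (4,5,6) vs (1,2,3): pooled t = 3/sqrt(2/3) ~ 3.674, df=4, p ~ 0.0213
        design = SampleDesign(
            ["a", "b", "c", "d", "e", "f"],
            ["treated"] * 3 + ["control"] * 3,
            ["6W", "10W", "12W"] * 2,
        )
        m = self._matrix([[4, 5, 6, 1, 2, 3]], design)
        (r,) = group_t_tests(m, design)
        t_expected = 3.0 / np.sqrt(1.0 * (1 / 3 + 1 / 3))  # pooled var = 1
        assert r.t_statistic == pytest.approx(t_expected, rel=1e-9)
        assert t_expected == pytest.approx(3.674, abs=1e-3)
        assert r.p_value == pytest.approx(2 * stats.t.sf(t_expected, df=4), rel=1e-9)
        assert r.p_value == pytest.approx(0.0213, abs=5e-4)

    def test_swapping_groups_flips_sign_keeps_p(self):
        design = _design(2)
        rng = np.random.default_rng(3)
        m = self._matrix(rng.normal(size=(5, 12)), design)
        flipped_design = SampleDesign(
            design.sample_ids,
            ["control" if g == "treated" else "treated" for g in design.group],
            design.timepoint,
        )
        a = group_t_tests(m, design)
        b = group_t_tests(m, flipped_design)
        for ra, rb in zip(a, b):
            assert ra.t_statistic == pytest.approx(-rb.t_statistic, rel=1e-12)
            assert ra.p_value == pytest.approx(rb.p_value, rel=1e-12)

    def test_type_one_error_on_null_bundle(self, null_bundle):
        results = group_t_tests(null_bundle.mrna_liver, null_bundle.design)
        frac = np.mean([r.significant for r in results])
        n = len(results)
        sd = np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < 3 * sd

    def test_zero_variance_both_groups_warns_p_one(self):
        design = _design(2)
        m = self._matrix([np.ones(12)], design)
        with pytest.warns(UserWarning, match="constant"):
            (r,) = group_t_tests(m, design)
        assert r.p_value == 1.0

    def test_welch_differs_with_unequal_variances(self):
        design = _design(2)
        rng = np.random.default_rng(8)
        rows = np.concatenate([rng.normal(0, 5, 6), rng.normal(0, 0.1, 6)])[None, :]
        m = self._matrix(rows, design)
        (student,) = group_t_tests(m, design, welch=False)
        (welch,) = group_t_tests(m, design, welch=True)
        assert student.p_value != pytest.approx(welch.p_value, rel=1e-6)
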