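"""Threshold learning, cross-validation, ROC, group statistics, and the
segment-wise Type IV detection rule."""

import itertools

import numpy as np
import pytest

from egmfrac import (
    REFERENCE_MODEL,
    ThresholdModel,
    classify_value,
    compare_groups,
    cross_validate,
    detect_type_iv,
    fit_thresholds,
    roc_one_vs_all,
)
from egmfrac.errors import ParameterError


def brute_force_best_accuracy(values, labels):
    """Independent oracle: best ordinal accuracy over every pair of cuts
    placed at the observed values themselves (plus sentinels)."""
    values = np.asarray(values)
    cuts = np.r_[np.unique(values), np.max(values) + 1.0]
    best = 0
    for c1, c2 in itertools.combinations(cuts, 2):
        pred = np.where(values < c1, "I", np.where(values < c2, "II", "III"))
        best = max(best, int(np.sum(pred == np.asarray(labels))))
    return best / len(values)


def random_instance(rng, n_per_class=4, spread=1.0):
    means = {"I": 1.0, "II": 1.8, "III": 2.6}
    values, labels = [], []
    for lab, mu in means.items():
        values.extend(rng.normal(mu, spread, n_per_class))
        labels.extend([lab] * n_per_class)
    return np.array(values), labels


class TestFitThresholds:
    def test_perfectly_separated(self):
        values = [1.0, 1.1, 1.7, 1.8, 2.5, 2.6]
        labels = ["I", "I", "II", "II", "III", "III"]
        model = fit_thresholds(values, labels)
        assert model.training_accuracy == 1.0
        assert 1.1 < model.T1 < 1.7
        assert 1.8 < model.T2 < 2.5

    def test_matches_brute_force_on_scrambled_sets(self, rng):
        for _ in range(25):
            values, labels = random_instance(rng, n_per_class=4, spread=0.8)
            model = fit_thresholds(values, labels)
            assert model.training_accuracy == pytest.approx(
                brute_force_best_accuracy(values, labels)
            )

    def test_maximal_margin_tie_break(self):
        # two wide gaps; cuts should bisect them
        values = [1.0, 1.05, 1.95, 2.0, 3.0, 3.05]
        labels = ["I", "I", "II", "II", "III", "III"]
        model = fit_thresholds(values, labels)
        assert model.T1 == pytest.approx((1.05 + 1.95) / 2)
        assert model.T2 == pytest.approx((2.0 + 3.0) / 2)

    def test_missing_class_rejected(self):
        with pytest.raises(ParameterError):
            fit_thresholds([1.0, 1.1, 2.0, 2.1], ["I", "I", "II", "II"])


class TestClassifyValue:
    def test_reference_thresholds_boundaries(self):
        assert classify_value(1.0, REFERENCE_MODEL) == "I"
        assert classify_value(1.3880, REFERENCE_MODEL) == "II"  # >= goes up
        assert classify_value(2.0326, REFERENCE_MODEL) == "III"
        assert classify_value(1.5, REFERENCE_MODEL) == "II"

    def test_zero_training_error_when_separable(self, rng):
        values, labels = random_instance(rng, n_per_class=5, spread=0.1)
        model = fit_thresholds(values, labels)
        assert all(
            classify_value(v, model) == lab for v, lab in zip(values, labels)
        )

    def test_model_ordering_enforced(self):
        with pytest.raises(ParameterError):
            ThresholdModel(T1=2.0, T2=1.0)


class TestCrossValidate:
    def test_separable_dataset_perfect(self, rng):
        values, labels = random_instance(rng, n_per_class=8, spread=0.1)
        assert cross_validate(values, labels, k=10, seed=0) == 1.0

    def test_permuted_labels_near_chance(self, rng):
        accs = []
        for seed in range(10):
            values, labels = random_instance(rng, n_per_class=8, spread=0.1)
            perm = np.random.default_rng(seed).permutation(len(labels))
            labels = [labels[i] for i in perm]
            accs.append(cross_validate(values, labels, k=6, seed=seed))
        assert abs(np.mean(accs) - 1 / 3) < 0.15

    def test_leave_one_out_boundary(self, rng):
        values, labels = random_instance(rng, n_per_class=8, spread=0.1)
        acc = cross_validate(values, labels, k=len(values), seed=0)
        assert acc == 1.0


class TestDetectTypeIV:
    def test_alternating_segments_give_iv(self):
        segs = [2.5, 2.5, 1.0, 2.5, 2.6, 2.4, 2.5, 2.5, 2.5, 2.5]
        d = detect_type_iv(segs, REFERENCE_MODEL)
        assert d.final_type == "IV"
        assert d.per_segment_types[2] == "I"

    def test_uniform_type_iii(self):
        d = detect_type_iv([2.5] * 10, REFERENCE_MODEL)
        assert d.final_type == "III"

    def test_uniform_type_i_never_starts_over(self):
        d = detect_type_iv([1.0, 1.1, 0.9, 1.2], REFERENCE_MODEL)
        assert d.final_type == "I"

    def test_i_and_ii_mix_without_iii_is_not_iv(self):
        # all segments below T2: the Type III branch never triggers
        d = detect_type_iv([1.0, 1.5, 1.2, 1.6], REFERENCE_MODEL)
        assert d.final_type in ("I", "II")

    def test_undefined_segments_skipped(self):
        d = detect_type_iv([None, 2.5, None, 1.0], REFERENCE_MODEL)
        assert d.final_type == "IV"
        assert d.per_segment_types[0] is None

    def test_all_undefined_flags_failure(self):
        d = detect_type_iv([None, None], REFERENCE_MODEL)
        assert d.analysis_failed
        assert d.final_type is None


class TestRocOneVsAll:
    def test_perfect_separation(self, rng):
        values, labels = random_instance(rng, n_per_class=8, spread=0.05)
        for pos in ("I", "III"):
            roc = roc_one_vs_all(values, labels, pos)
            assert roc.auc == 1.0
            assert roc.youden_index == 1.0
            assert roc.sensitivity == 1.0 and roc.specificity == 1.0

    def test_random_labels_near_half(self, rng):
        aucs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            values = r.normal(2.0, 0.5, 30)
            labels = list(r.choice(["I", "II", "III"], 30))
            if "III" not in labels or len(set(labels)) < 2:
                continue
            aucs.append(roc_one_vs_all(values, labels, "III").auc)
        assert abs(np.mean(aucs) - 0.5) < 0.12

    def test_monotone_transform_invariance(self, rng):
        values, labels = random_instance(rng, n_per_class=6, spread=0.6)
        a = roc_one_vs_all(values, labels, "III").auc
        b = roc_one_vs_all(np.exp(values), labels, "III").auc
        assert a == pytest.approx(b)

    def test_one_class_rejected(self):
        with pytest.raises(ParameterError):
            roc_one_vs_all([1.0, 2.0], ["I", "I"], "III")


class TestCompareGroups:
    def test_well_separated_groups(self, rng):
        values, labels = random_instance(rng, n_per_class=8, spread=0.1)
        rep = compare_groups(values, labels)
        assert rep["omnibus"]["test"] == "kruskal-wallis"
        assert rep["omnibus"]["p"] < 0.001
        assert rep["bonferroni_factor"] == 3
        assert all(
            v["p_corrected"] < 0.01 for v in rep["pairwise_mann_whitney"].values()
        )

    def test_identical_groups_not_significant(self, rng):
        base = rng.normal(2.0, 0.3, 10)
        values = np.r_[base, base]
        labels = ["I"] * 10 + ["II"] * 10
        rep = compare_groups(values, labels)
        assert rep["omnibus"]["p"] > 0.9
        assert all(
            v["p_corrected"] > 0.9 for v in rep["pairwise_mann_whitney"].values()
        )

    def test_two_groups_single_pairwise(self, rng):
        values = np.r_[rng.normal(1, 0.1, 5), rng.normal(2, 0.1, 5)]
        labels = ["I"] * 5 + ["III"] * 5
        rep = compare_groups(values, labels)
        assert rep["bonferroni_factor"] == 1
        assert rep["omnibus"]["test"] == "mann-whitney"

    def test_tiny_group_skips_shapiro(self, rng):
        values = np.r_[rng.normal(1, 0.1, 2), rng.normal(2, 0.1, 6)]
        labels = ["I"] * 2 + ["III"] * 6
        rep = compare_groups(values, labels)
        assert rep["shapiro_wilk"]["I"] is None
        assert rep["notices"]
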