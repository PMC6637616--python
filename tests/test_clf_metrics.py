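"""Classification metrics against brute-force recounts and concordance oracles.

The screening-study worked example used throughout: 412 healthy images of
which 391 are predicted healthy and 21 glaucoma; 139 glaucomatous images of
which 48 are predicted glaucoma and 91 healthy.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fundlocate as fl
from fundlocate.clf_metrics import (
    CLASSES,
    UndefinedMetricError,
    confusion,
    f1,
    kfold_split,
    precision,
    recall,
    report,
    roc_auc,
    sensitivity_at_specificity,
    specificity,
    stratified_kfold_split,
)


def screening_outcome():
    """Label/prediction lists encoding the worked screening-study outcome."""
    labels = ["healthy"] * 412 + ["glaucoma"] * 139
    preds = (
        ["healthy"] * 391 + ["glaucoma"] * 21
        + ["glaucoma"] * 48 + ["healthy"] * 91
    )
    return labels, preds


class TestConfusion:
    def test_all_correct_has_no_errors(self):
        labels = ["healthy", "glaucoma", "healthy"]
        c = confusion(labels, labels)
        for cls in CLASSES:
            assert c[cls]["fp"] == 0 and c[cls]["fn"] == 0

    def test_screening_outcome_counts(self):
        labels, preds = screening_outcome()
        c = confusion(labels, preds)
        assert c["healthy"]["tp"] == 391
        assert c["healthy"]["fp"] == 91
        assert c["healthy"]["fn"] == 21
        assert c["glaucoma"]["tp"] == 48

    def test_binary_complementarity(self, rng):
        labels = [CLASSES[i] for i in rng.integers(0, 2, 200)]
        preds = [CLASSES[i] for i in rng.integers(0, 2, 200)]
        c = confusion(labels, preds)
        assert c["healthy"]["tp"] == c["glaucoma"]["tn"]
        assert c["healthy"]["fp"] == c["glaucoma"]["fn"]

    def test_length_mismatch_and_empty_raise(self):
        with pytest.raises(ValueError):
            confusion(["healthy"], [])
        with pytest.raises(ValueError):
            confusion([], [])

    def test_brute_force_recount_random(self, rng):
        labels = [CLASSES[i] for i in rng.integers(0, 2, 500)]
        preds = [CLASSES[i] for i in rng.integers(0, 2, 500)]
        c = confusion(labels, preds)
        for cls in CLASSES:
            tp = sum(l == cls == p for l, p in zip(labels, preds))
            support = sum(l == cls for l in labels)
            assert c[cls]["tp"] == tp
            assert c.support(cls) == support
            assert sum(c[cls].values()) == 500


class TestMetricFormulas:
    def test_screening_precision_recall(self):
        labels, preds = screening_outcome()
        c = confusion(labels, preds)
        assert precision(c, "healthy") == pytest.approx(81.12, abs=0.005)
        assert recall(c, "healthy") == pytest.approx(94.90, abs=0.005)
        assert precision(c, "glaucoma") == pytest.approx(69.57, abs=0.005)
        assert recall(c, "glaucoma") == pytest.approx(34.53, abs=0.005)

    def test_screening_f1(self):
        assert f1(81.12, 94.90) == pytest.approx(0.8747, abs=5e-5)
        assert f1(69.57, 34.53) == pytest.approx(0.4615, abs=5e-5)

    def test_f1_identity_when_p_equals_r(self):
        for p in (10.0, 50.0, 99.0):
            assert f1(p, p) == pytest.approx(p / 100.0)

    def test_f1_both_zero_convention(self):
        assert f1(0.0, 0.0) == 0.0

    @given(st.floats(0.0, 100.0), st.floats(0.0, 100.0))
    @settings(max_examples=200, deadline=None)
    def test_f1_bounded_by_harmonic_mean_property(self, p, r):
        # a mean lies between its arguments (degenerate 0,0 maps to 0)
        v = 100.0 * f1(p, r)
        if p == 0 and r == 0:
            assert v == 0.0
        else:
            assert min(p, r) - 1e-9 <= v <= max(p, r) + 1e-9

    @given(st.lists(st.sampled_from([0, 1]), min_size=4, max_size=60),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_specificity_equals_other_class_recall(self, bits, seed):
        rng = np.random.default_rng(seed)
        labels = [CLASSES[b] for b in bits]
        preds = [CLASSES[i] for i in rng.integers(0, 2, len(bits))]
        c = confusion(labels, preds)
        for cls, other in (("healthy", "glaucoma"), ("glaucoma", "healthy")):
            try:
                s = specificity(c, cls)
            except UndefinedMetricError:
                continue
            assert s == pytest.approx(recall(c, other))

    def test_specificity_complementarity(self):
        labels, preds = screening_outcome()
        c = confusion(labels, preds)
        # specificity of glaucoma = recall of healthy
        assert specificity(c, "glaucoma") == pytest.approx(recall(c, "healthy"))
        assert specificity(c, "glaucoma") == pytest.approx(94.90, abs=0.005)

    def test_degenerate_denominators_raise(self):
        c = confusion(["healthy", "healthy"], ["healthy", "healthy"])
        with pytest.raises(UndefinedMetricError):
            precision(c, "glaucoma")  # no glaucoma predictions
        with pytest.raises(UndefinedMetricError):
            recall(c, "glaucoma")  # zero support
        with pytest.raises(UndefinedMetricError):
            specificity(c, "healthy")  # no healthy negatives

    def test_zero_tp_with_fp_gives_zero_precision(self):
        c = confusion(["healthy"] * 5, ["glaucoma"] * 5)
        assert precision(c, "glaucoma") == 0.0

    def test_eqs_agree_with_recount_on_random_runs(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 80))
            labels = [CLASSES[i] for i in rng.integers(0, 2, n)]
            preds = [CLASSES[i] for i in rng.integers(0, 2, n)]
            if len(set(labels)) < 2 or len(set(preds)) < 2:
                continue
            c = confusion(labels, preds)
            for cls in CLASSES:
                tp = sum(l == cls == p for l, p in zip(labels, preds))
                pp = sum(p == cls for p in preds)
                sup = sum(l == cls for l in labels)
                assert precision(c, cls) == pytest.approx(100 * tp / pp)
                assert recall(c, cls) == pytest.approx(100 * tp / sup)


class TestReport:
    def test_screening_report_totals(self):
        labels, preds = screening_outcome()
        rep = report(labels, preds)
        assert rep.total_precision == pytest.approx(78.21, abs=0.005)
        assert rep.accuracy == pytest.approx(79.67, abs=0.005)
        assert rep.total_f1 == pytest.approx(0.7705, abs=5e-5)
        assert rep.per_class["healthy"].support == 412
        assert rep.per_class["glaucoma"].support == 139
        assert rep.n == 551

    def test_all_correct_balanced(self):
        labels = ["healthy"] * 10 + ["glaucoma"] * 10
        rep = report(labels, labels)
        assert rep.accuracy == 100.0
        assert rep.total_precision == 100.0
        assert rep.total_f1 == pytest.approx(1.0)

    def test_three_example_hand_computation(self):
        rep = report(["healthy", "healthy", "glaucoma"], ["healthy", "glaucoma", "glaucoma"])
        assert rep.accuracy == pytest.approx(100 * 2 / 3)
        assert rep.per_class["healthy"].precision == pytest.approx(100.0)
        assert rep.per_class["healthy"].recall == pytest.approx(50.0)

    def test_totals_are_support_weighted(self, rng):
        labels = [CLASSES[i] for i in rng.integers(0, 2, 300)]
        preds = [CLASSES[i] for i in rng.integers(0, 2, 300)]
        rep = report(labels, preds)
        manual = sum(
            rep.per_class[c].precision * rep.per_class[c].support for c in CLASSES
        ) / 300
        assert rep.total_precision == pytest.approx(manual)


def concordance_auc(scores, labels, positive="glaucoma"):
    """Oracle: mean over all (pos, neg) pairs of 1/0.5/0 concordance."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = ["glaucoma", "glaucoma", "healthy", "healthy"]
        assert roc_auc(scores, labels).auc == pytest.approx(1.0)

    def test_tiny_concordance_examples(self):
        assert roc_auc([0.9, 0.8, 0.7], ["glaucoma", "glaucoma", "healthy"]).auc == 1.0
        assert roc_auc([0.9, 0.6, 0.7], ["glaucoma", "glaucoma", "healthy"]).auc == 0.5

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2024)
        scores = rng.uniform(size=1000)
        labels = [CLASSES[i] for i in rng.integers(0, 2, 1000)]
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_matches_concordance_oracle_with_ties(self, rng):
        for _ in range(40):
            n = int(rng.integers(5, 60))
            scores = rng.integers(0, 8, n) / 7.0  # coarse grid forces ties
            labels = [CLASSES[i] for i in rng.integers(0, 2, n)]
            if len(set(labels)) < 2:
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                concordance_auc(scores, labels), abs=1e-12
            )

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], ["healthy", "healthy"])


class TestSensitivityAtSpecificity:
    def test_perfect_classifier_is_100_everywhere(self):
        curve = roc_auc([0.9, 0.8, 0.2, 0.1], ["glaucoma", "glaucoma", "healthy", "healthy"])
        for target in (50, 85, 100):
            assert sensitivity_at_specificity(curve, target) == 100.0

    def test_step_convention_on_two_point_curve(self):
        curve = fl.ROCCurve(points=[(100.0, 0.0), (0.0, 100.0)], thresholds=[np.inf, 0.0], auc=0.5)
        assert sensitivity_at_specificity(curve, 85.0) == 0.0

    def test_hand_built_curve(self):
        points = [(100.0, 0.0), (95.0, 40.0), (90.0, 60.0), (80.0, 75.0), (0.0, 100.0)]
        curve = fl.ROCCurve(points=points, thresholds=[np.inf, 0.9, 0.7, 0.5, 0.1], auc=0.8)
        assert sensitivity_at_specificity(curve, 85.0) == 60.0
        assert sensitivity_at_specificity(curve, 95.0) == 40.0
        assert sensitivity_at_specificity(curve, 50.0) == 75.0

    def test_target_out_of_range(self):
        curve = fl.ROCCurve(points=[(100.0, 0.0)], thresholds=[np.inf], auc=0.5)
        for bad in (0, -5, 101):
            with pytest.raises(ValueError):
                sensitivity_at_specificity(curve, bad)


class TestKfold:
    def test_650_ids_into_10_folds_of_65(self):
        ids = [f"img{i}" for i in range(650)]
        split = kfold_split(ids, 10, seed=3)
        sizes = [len(split.fold_ids(f)) for f in range(10)]
        assert sizes == [65] * 10

    def test_uneven_sizes_differ_by_at_most_one(self):
        split = kfold_split(list("abcdefg"), 3, seed=0)
        sizes = sorted(len(split.fold_ids(f)) for f in range(3))
        assert sizes == [2, 2, 3]

    def test_deterministic_under_seed(self):
        ids = [f"i{i}" for i in range(40)]
        assert kfold_split(ids, 5, seed=9).assignment == kfold_split(ids, 5, seed=9).assignment

    def test_partition_is_disjoint_and_complete(self):
        ids = [f"i{i}" for i in range(53)]
        split = kfold_split(ids, 7, seed=1)
        all_ids = [i for f in range(7) for i in split.fold_ids(f)]
        assert sorted(all_ids) == sorted(ids)

    def test_k_larger_than_n_raises(self):
        with pytest.raises(ValueError):
            kfold_split(["a", "b"], 3)

    def test_stratified_preserves_class_balance(self):
        ids = [f"i{i}" for i in range(100)]
        labels = ["glaucoma" if i < 20 else "healthy" for i in range(100)]
        split = stratified_kfold_split(ids, labels, 5, seed=2)
        for f in range(5):
            fold = split.fold_ids(f)
            n_g = sum(1 for i in fold if labels[int(i[1:])] == "glaucoma")
            assert n_g == 4
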