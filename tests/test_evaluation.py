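"""Confusion metrics, kappa oracles and window-size selection."""
import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

import burstclass as bc
from burstclass.errors import FitError, UndefinedKappaError
from burstclass.evaluation import (ConfusionMatrix, PerformanceReport,
                                   WindowSizeCurve, per_class_metrics,
                                   smooth_and_select)


def _brute_force_metrics(truth, pred, cls):
    """One-vs-rest metric computation straight from the label pairs."""
    tp = sum(t == cls and p == cls for t, p in zip(truth, pred))
    fn = sum(t == cls and p != cls for t, p in zip(truth, pred))
    fp = sum(t != cls and p == cls for t, p in zip(truth, pred))
    tn = len(truth) - tp - fn - fp
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    return recall, precision, (tp + tn) / len(truth)


def _brute_force_kappa(truth, pred):
    n = len(truth)
    classes = sorted(set(truth) | set(pred))
    po = sum(t == p for t, p in zip(truth, pred)) / n
    pe = sum((truth.count(c) / n) * (pred.count(c) / n) for c in classes)
    return (po - pe) / (1 - pe)


class TestConfusion:
    def test_perfect_agreement_is_diagonal(self):
        labels = ["a", "b", "c", "a", "b", "c", "a", "a", "b", "c"]
        cm = bc.confusion(labels, labels)
        assert np.trace(cm.counts) == 10 == cm.total

    def test_all_predicted_one_class_single_column(self):
        truth = ["feeding", "resting", "trotting", "walking"]
        pred = ["grooming"] * 4
        cm = bc.confusion(truth, pred)
        col = list(cm.pred_classes).index("grooming")
        assert cm.counts[:, col].sum() == 4
        assert cm.counts.sum() == 4
        assert all(cm.counts[:, j].sum() == 0
                   for j in range(len(cm.pred_classes)) if j != col)

    def test_empty_input(self):
        cm = bc.confusion([], [])
        assert cm.total == 0

    def test_other_kept_as_extra_predicted_column(self):
        cm = bc.confusion(["a", "b"], ["a", "other"])
        assert cm.pred_classes[-1] == "other"
        assert "other" not in cm.truth_classes

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bc.confusion(["a"], ["a", "b"])


class TestPerClassMetrics:
    def test_perfect_three_class(self):
        labels = ["a", "b", "c"] * 4
        cm = bc.confusion(labels, labels)
        recall, precision, accuracy, und = per_class_metrics(cm)
        assert all(v == 1.0 for v in recall.values())
        assert all(v == 1.0 for v in precision.values())
        assert all(v == 1.0 for v in accuracy.values())
        assert not und

    def test_hand_counted_two_class(self):
        # confusion [[8,2],[1,9]]: class-1 TP=8 FN=2 FP=1 TN=9
        truth = ["c1"] * 10 + ["c2"] * 10
        pred = ["c1"] * 8 + ["c2"] * 2 + ["c2"] * 9 + ["c1"] * 1
        cm = bc.confusion(truth, pred)
        recall, precision, accuracy, _ = per_class_metrics(cm)
        assert recall["c1"] == pytest.approx(0.8)
        assert precision["c1"] == pytest.approx(8 / 9)
        assert accuracy["c1"] == pytest.approx(0.85)

    def test_class_absent_from_truth_flagged_zero(self):
        cm = ConfusionMatrix(("a", "b"), ("a", "b"),
                             np.array([[3, 0], [0, 0]]))
        recall, _, _, und = per_class_metrics(cm)
        assert recall["b"] == 0.0 and "recall:b" in und

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(0)
        classes = ["a", "b", "c", "d"]
        for _ in range(1000):
            n = int(rng.integers(10, 60))
            truth = list(rng.choice(classes, n))
            pred = list(rng.choice(classes, n))
            cm = bc.confusion(truth, pred, classes=classes)
            recall, precision, accuracy, _ = per_class_metrics(cm)
            for cls in classes:
                r, p, a = _brute_force_metrics(truth, pred, cls)
                assert abs(recall[cls] - r) < 1e-12
                assert abs(precision[cls] - p) < 1e-12
                assert abs(accuracy[cls] - a) < 1e-12


class TestCohensKappa:
    def test_identity_matrix_is_one(self):
        cm = ConfusionMatrix(("a", "b", "c"), ("a", "b", "c"), np.eye(3, dtype=int) * 5)
        assert bc.cohens_kappa(cm) == pytest.approx(1.0)

    def test_independent_margins_is_zero(self):
        row = np.array([40, 10])
        col = np.array([30, 20])
        counts = np.outer(row, col) // 1  # outer product => po == pe
        cm = ConfusionMatrix(("a", "b"), ("a", "b"), counts)
        assert bc.cohens_kappa(cm) == pytest.approx(0.0, abs=1e-12)

    def test_matches_label_pair_oracle_and_sklearn(self):
        rng = np.random.default_rng(1)
        classes = ["w", "x", "y", "z"]
        for _ in range(200):
            truth = list(rng.choice(classes, 200))
            pred = list(rng.choice(classes, 200))
            cm = bc.confusion(truth, pred, classes=classes)
            k = bc.cohens_kappa(cm)
            assert k == pytest.approx(_brute_force_kappa(truth, pred), abs=1e-12)
            assert k == pytest.approx(cohen_kappa_score(truth, pred), abs=1e-9)

    def test_degenerate_all_one_cell(self):
        cm = ConfusionMatrix(("a",), ("a",), np.array([[7]]))
        with pytest.raises(UndefinedKappaError):
            bc.cohens_kappa(cm)

    def test_printed_chance_variant_differs_in_general(self):
        truth = ["a"] * 6 + ["b"] * 4
        pred = ["a"] * 4 + ["b"] * 2 + ["b"] * 3 + ["a"] * 1
        cm = bc.confusion(truth, pred)
        k_std = bc.cohens_kappa(cm, chance="standard")
        k_alt = bc.cohens_kappa(cm, chance="printed")
        assert np.isfinite(k_alt) and k_std != k_alt


class TestSelectionScore:
    def _report(self, recall, precision, other):
        return PerformanceReport(recall=recall, precision=precision,
                                 accuracy={}, kappa=0.0, other_proportion=other)

    def test_perfect_is_one(self):
        r = self._report({"a": 1.0, "b": 1.0}, {"a": 1.0, "b": 1.0}, 0.0)
        assert bc.selection_score(r) == 1.0

    def test_stated_arithmetic(self):
        r = self._report({"a": 0.8}, {"a": 0.6}, 0.1)
        assert bc.selection_score(r) == pytest.approx((0.8 + 0.6 + 0.9) / 3)

    def test_all_zero_with_full_rejection_is_zero(self):
        r = self._report({"a": 0.0}, {"a": 0.0}, 1.0)
        assert bc.selection_score(r) == 0.0

    def test_invariant_to_class_order(self):
        r1 = self._report({"a": 0.2, "b": 0.9}, {"a": 0.5, "b": 0.7}, 0.05)
        r2 = self._report({"b": 0.9, "a": 0.2}, {"b": 0.7, "a": 0.5}, 0.05)
        assert bc.selection_score(r1) == pytest.approx(bc.selection_score(r2))


class TestSmoothAndSelect:
    def test_exact_parabola_recovers_peak(self):
        sizes = np.arange(20, 111)
        for peak in (45, 79, 95):
            y = 0.9 - 5e-4 * (sizes - peak) ** 2
            curve = WindowSizeCurve(sizes, y)
            assert smooth_and_select(curve) == peak

    def test_strictly_increasing_chooses_largest(self):
        sizes = np.arange(20, 111)
        curve = WindowSizeCurve(sizes, 0.005 * sizes.astype(float))
        assert smooth_and_select(curve) == 110

    def test_flat_curve_chooses_smallest(self):
        sizes = np.arange(20, 111)
        curve = WindowSizeCurve(sizes, np.full(len(sizes), 0.5))
        assert smooth_and_select(curve) == 20

    def test_linear_fit_has_constant_difference_quotients(self):
        sizes = np.arange(20, 111)
        curve = WindowSizeCurve(sizes, 0.002 * sizes + 0.1)
        smooth_and_select(curve)
        assert np.ptp(curve.slopes) < 1e-8

    def test_too_few_points(self):
        with pytest.raises(FitError):
            smooth_and_select(WindowSizeCurve(np.array([20, 30, 40]),
                                              np.array([0.1, 0.2, 0.3])))


class TestSweep:
    @pytest.fixture(scope="class")
    def tiny_bursts(self):
        return bc.generate_captive_dataset(
            {c: 8 for c in bc.CAPTIVE_COUNTS}, seed=5)

    def test_single_size_full_burst(self, tiny_bursts):
        clf = bc.WindowClassifier(kind="ann", max_iter=15, random_state=0)
        curve = bc.sweep_window_sizes(tiny_bursts, sizes=[110], seed=0, clf=clf)
        assert len(curve.raw_scores) == 1
        assert 0.0 <= curve.raw_scores[0] <= 1.0

    def test_identical_seed_identical_curve(self, tiny_bursts):
        clf = bc.WindowClassifier(kind="ann", max_iter=15, random_state=0)
        c1 = bc.sweep_window_sizes(tiny_bursts, sizes=[40, 80], seed=2, clf=clf)
        c2 = bc.sweep_window_sizes(tiny_bursts, sizes=[40, 80], seed=2, clf=clf)
        np.testing.assert_array_equal(c1.raw_scores, c2.raw_scores)
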