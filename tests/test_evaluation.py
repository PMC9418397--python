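import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermofoot.evaluation import (
    EvalReport,
    classwise_metrics,
    confusion,
    macro_average,
    stratified_folds,
)


def brute_force_metrics(y_true, y_pred, num_classes):
    """Independent oracle: explicit per-sample enumeration of TP/FP/FN/TN."""
    n = len(y_true)
    out = {}
    for c in range(num_classes):
        tp = fp = fn = tn = 0
        for t, p in zip(y_true, y_pred):
            if t == c and p == c:
                tp += 1
            elif t != c and p == c:
                fp += 1
            elif t == c and p != c:
                fn += 1
            else:
                tn += 1
        sens = tp / (tp + fn) if tp + fn else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        out[c] = {
            "accuracy": (tp + tn) / n,
            "specificity": tn / (tn + fp) if tn + fp else 0.0,
            "sensitivity": sens,
            "precision": prec,
            "f_measure": 2 * prec * sens / (prec + sens) if prec + sens else 0.0,
        }
    return out


class TestStratifiedFolds:
    def test_balanced_two_class(self):
        labels = np.array([0] * 50 + [1] * 50)
        fs = stratified_folds(labels, k=5, seed=0)
        for fold in range(5):
            val = labels[fs.val_indices(fold)]
            assert (val == 0).sum() == 10
            assert (val == 1).sum() == 10

    def test_partition_property(self):
        labels = np.random.default_rng(0).integers(0, 3, 60)
        fs = stratified_folds(labels, k=4, seed=1)
        all_val = np.concatenate([fs.val_indices(f) for f in range(4)])
        assert sorted(all_val) == list(range(60))
        for f in range(4):
            assert not set(fs.val_indices(f)) & set(fs.train_indices(f))

    def test_same_seed_identical(self):
        labels = np.random.default_rng(1).integers(0, 4, 80)
        f1 = stratified_folds(labels, k=5, seed=9)
        f2 = stratified_folds(labels, k=5, seed=9)
        assert np.array_equal(f1.assignments, f2.assignments)

    def test_small_class_error_names_class(self):
        labels = np.array([0] * 20 + [3] * 2)
        with pytest.raises(ValueError, match="class 3"):
            stratified_folds(labels, k=5)

    @given(
        counts=st.lists(st.integers(min_value=5, max_value=40), min_size=2, max_size=6),
        seed=st.integers(min_value=0, max_value=1000),
    )
    @settings(max_examples=50, deadline=None)
    def test_stratification_within_one_sample(self, counts, seed):
        labels = np.concatenate([np.full(n, c) for c, n in enumerate(counts)])
        fs = stratified_folds(labels, k=5, seed=seed)
        for cls, n in enumerate(counts):
            per_fold = [
                (labels[fs.val_indices(f)] == cls).sum() for f in range(5)
            ]
            assert max(per_fold) - min(per_fold) <= 1


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        y = np.array([0, 0, 1, 2, 2, 2])
        cm = confusion(y, y, 3)
        assert np.array_equal(cm, np.diag([2, 1, 3]))

    def test_direct_enumeration(self):
        cm = confusion([0, 0, 1, 1], [0, 1, 1, 1], 2)
        assert np.array_equal(cm, [[1, 1], [0, 2]])

    def test_total_equals_sample_count(self, rng):
        y_true = rng.integers(0, 4, 57)
        y_pred = rng.integers(0, 4, 57)
        assert confusion(y_true, y_pred, 4).sum() == 57

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([0, 1], [0], 2)


class TestClasswiseMetrics:
    def test_perfect_diagonal_all_ones(self):
        report = classwise_metrics(np.diag([5, 3, 7]))
        for m in report.per_class.values():
            assert m.as_dict() == pytest.approx(
                {k: 1.0 for k in m.as_dict()}
            )

    def test_hand_evaluated_two_class(self):
        # cm [[8,2],[1,9]]: class 0 sens .8, spec .9, prec 8/9, acc .85
        report = classwise_metrics(np.array([[8, 2], [1, 9]]))
        c0 = report.per_class[0]
        assert c0.sensitivity == pytest.approx(0.8)
        assert c0.specificity == pytest.approx(0.9)
        assert c0.precision == pytest.approx(8 / 9)
        assert c0.accuracy == pytest.approx(0.85)
        assert c0.f_measure == pytest.approx(2 * (8 / 9) * 0.8 / (8 / 9 + 0.8))

    def test_f_equals_precision_when_equal_to_sensitivity(self):
        # when precision == sensitivity the harmonic mean collapses to them;
        # printed reference row: precision .9836, sensitivity .9836, F .9836
        report = classwise_metrics(np.array([[60, 1], [1, 62]]))
        c0 = report.per_class[0]
        assert c0.precision == pytest.approx(c0.sensitivity)
        assert c0.f_measure == pytest.approx(c0.precision)

    def test_absent_class_flagged_undefined(self):
        cm = np.array([[4, 0, 0], [0, 5, 0], [0, 0, 0]])
        with pytest.warns(UserWarning, match="undefined"):
            report = classwise_metrics(cm)
        assert not report.per_class[2].defined
        macro = macro_average(report)
        assert macro["sensitivity"] == pytest.approx(1.0)  # class 2 excluded

    def test_oracle_equivalence_random_matrices(self, rng):
        import warnings

        for _ in range(200):
            k = int(rng.integers(2, 7))
            n = int(rng.integers(5, 60))
            y_true = rng.integers(0, k, n)
            y_pred = rng.integers(0, k, n)
            cm = confusion(y_true, y_pred, k)
            with warnings.catch_warnings():
                # random matrices legitimately produce absent classes
                warnings.simplefilter("ignore", UserWarning)
                report = classwise_metrics(cm)
            oracle = brute_force_metrics(y_true, y_pred, k)
            for c in range(k):
                if not report.per_class[c].defined:
                    continue
                assert report.per_class[c].as_dict() == pytest.approx(oracle[c])

    def test_micro_sensitivity_equals_overall_accuracy(self, rng):
        y_true = rng.integers(0, 5, 120)
        y_pred = rng.integers(0, 5, 120)
        cm = confusion(y_true, y_pred, 5)
        report = classwise_metrics(cm)
        tp_sum = sum(cm[c, c] for c in range(5))
        support_sum = sum(
            m.support for m in report.per_class.values()
        )
        assert support_sum == 120  # sum over classes of TP+FN = N
        micro_sens = tp_sum / support_sum
        assert micro_sens == pytest.approx((y_true == y_pred).mean())


class TestMacroAverage:
    def test_identical_classes(self):
        report = classwise_metrics(np.diag([4, 4]))
        macro = macro_average(report)
        assert macro == pytest.approx({k: 1.0 for k in macro})

    def test_printed_sensitivity_average(self):
        sens = [0.9365, 0.9844, 1.0000, 0.9836, 0.9677, 0.9365]
        assert round(float(np.mean(sens)), 4) == 0.9681

    def test_printed_specificity_average(self):
        spec = [0.9968, 0.9936, 0.9936, 0.9968, 0.9840, 0.9968]
        assert round(float(np.mean(spec)), 4) == 0.9936

    def test_degenerate_one_class_report(self):
        cm = np.array([[3, 1], [2, 4]])
        report = classwise_metrics(cm)
        solo = EvalReport(
            per_class={0: report.per_class[0]},
            confusion_matrix=report.confusion_matrix,
        )
        macro = macro_average(solo)
        assert macro == pytest.approx(report.per_class[0].as_dict())

    def test_report_frame_layout(self):
        df = classwise_metrics(np.diag([2, 3])).to_frame()
        assert list(df.index) == ["Class 0", "Class 1", "Average"]
        assert list(df.columns) == [
            "accuracy", "specificity", "sensitivity", "precision", "f_measure",
        ]
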