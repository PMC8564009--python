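import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from msibeef.evaluate import (
    ClassifierSpec,
    ConfusionMatrix,
    SplitSpec,
    cross_validate,
    make_split,
    metrics,
    train_predict,
)
from msibeef.fusion import FeatureMatrix


def labeled_matrix(labels, n_features=3, seed=0, shift_per_class=0.0):
    """Random features; optionally linearly separable by class."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    values = rng.normal(size=(len(labels), n_features))
    if shift_per_class:
        for i, cls in enumerate(np.unique(labels)):
            values[labels == cls] += i * shift_per_class
    return FeatureMatrix(values, tuple(f"f{i}" for i in range(n_features)),
                         ("MS",) * n_features, labels=labels)


def reference_labels():
    return np.repeat(["sirloin", "flank", "shank"], [200, 160, 195])


class TestSplit:
    def test_stratified_proportional_allocation(self):
        fm = labeled_matrix(reference_labels())
        cal, pred = make_split(fm, SplitSpec(seed=3))
        assert cal.n_samples == 445 and pred.n_samples == 110
        counts = {c: int((pred.labels == c).sum()) for c in ("sirloin", "flank", "shank")}
        assert abs(counts["sirloin"] - 40) <= 1
        assert abs(counts["flank"] - 32) <= 1
        assert abs(counts["shank"] - 39) <= 1

    def test_same_seed_reproduces_membership(self):
        fm = labeled_matrix(reference_labels())
        a = make_split(fm, SplitSpec(seed=9))
        b = make_split(fm, SplitSpec(seed=9))
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].values, b[1].values)

    def test_partition_is_disjoint_and_exhaustive(self):
        fm = labeled_matrix(reference_labels())
        cal, pred = make_split(fm, SplitSpec(seed=1))
        # feature rows are unique random reals: identify membership by value
        all_rows = {tuple(r) for r in fm.values}
        cal_rows = {tuple(r) for r in cal.values}
        pred_rows = {tuple(r) for r in pred.values}
        assert cal_rows | pred_rows == all_rows
        assert not (cal_rows & pred_rows)

    def test_size_mismatch_rejected(self):
        fm = labeled_matrix(["a"] * 10)
        with pytest.raises(ValueError, match="split expects"):
            make_split(fm, SplitSpec(n_calibration=5, n_prediction=4))


class TestCrossValidate:
    def test_returns_k_fold_accuracies(self):
        fm = labeled_matrix(np.repeat(["a", "b"], 30), shift_per_class=10.0)
        cv = cross_validate(fm, ClassifierSpec("lda"), k=10, seed=0)
        assert len(cv.fold_accuracies) == 10

    def test_separable_classes_reach_full_accuracy(self):
        fm = labeled_matrix(np.repeat(["a", "b"], 40), shift_per_class=12.0)
        for kind in ("lda", "linear_svm", "random_forest"):
            cv = cross_validate(fm, ClassifierSpec(kind), k=5, seed=0)
            assert cv.mean_accuracy == pytest.approx(100.0)

    def test_random_labels_score_near_chance(self):
        rng = np.random.default_rng(11)
        accs = []
        for seed in range(3):
            labels = rng.permutation(np.repeat(["a", "b", "c"], 60))
            fm = labeled_matrix(labels, n_features=5, seed=seed)
            accs.append(cross_validate(fm, ClassifierSpec("lda"), k=5, seed=seed).mean_accuracy)
        assert np.mean(accs) == pytest.approx(100 / 3, abs=5.0)

    def test_class_smaller_than_k_rejected(self):
        fm = labeled_matrix(np.repeat(["a", "b"], [30, 5]))
        with pytest.raises(ValueError, match="10-fold"):
            cross_validate(fm, ClassifierSpec("lda"), k=10)

    def test_bit_identical_given_seed(self):
        fm = labeled_matrix(np.repeat(["a", "b", "c"], 25), shift_per_class=1.0)
        a = cross_validate(fm, ClassifierSpec("random_forest", seed=5), k=5, seed=5)
        b = cross_validate(fm, ClassifierSpec("random_forest", seed=5), k=5, seed=5)
        assert a == b


class TestTrainPredict:
    def test_forest_memorizes_training_set(self):
        fm = labeled_matrix(np.repeat(["a", "b", "c"], 15), shift_per_class=0.5, seed=4)
        result = train_predict(fm, fm, ClassifierSpec("random_forest", seed=1))
        assert result.accuracy == pytest.approx(100.0)

    def test_confusion_rows_sum_to_class_counts(self):
        labels = np.repeat(["sirloin", "flank", "shank"], [20, 16, 19])
        cal = labeled_matrix(labels, seed=1, shift_per_class=0.8)
        pred = labeled_matrix(labels, seed=2, shift_per_class=0.8)
        result = train_predict(cal, pred, ClassifierSpec("lda"))
        np.testing.assert_array_equal(result.confusion.counts.sum(axis=1), [20, 16, 19])
        assert result.confusion.total == 55

    def test_single_class_prediction_accuracy_equals_recall(self):
        cal = labeled_matrix(np.repeat(["a", "b"], 20), shift_per_class=1.0, seed=3)
        pred = labeled_matrix(np.repeat(["a"], 12), seed=9, shift_per_class=1.0)
        result = train_predict(cal, pred, ClassifierSpec("linear_svm"))
        idx = list(result.confusion.class_names).index("a")
        assert result.accuracy == pytest.approx(result.per_class["a"]["recall"])
        assert result.confusion.counts[idx].sum() == 12

    def test_schema_mismatch_rejected(self):
        cal = labeled_matrix(np.repeat(["a", "b"], 10))
        pred = FeatureMatrix(cal.values[:4], ("x0", "x1", "x2"), cal.modalities,
                             labels=cal.labels[:4])
        with pytest.raises(ValueError, match="schema"):
            train_predict(cal, pred, ClassifierSpec("lda"))


class TestMetrics:
    def test_one_vs_rest_worked_example(self):
        # TP=8, FN=2 (first row), FP=1, TN=9
        cm = ConfusionMatrix(np.array([[8, 2], [1, 9]]), class_names=("pos", "neg"))
        m = metrics(cm, 0)
        assert m.accuracy == pytest.approx(85.0)
        assert m.precision == pytest.approx(88.888888888, abs=1e-6)
        assert m.recall == pytest.approx(80.0)
        assert not m.undefined

    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(np.diag([10, 12, 9]))
        for i in range(3):
            m = metrics(cm, i)
            assert (m.accuracy, m.precision, m.recall) == (100.0, 100.0, 100.0)

    def test_absent_class_flagged_undefined(self):
        cm = ConfusionMatrix(np.array([[5, 0, 0], [0, 4, 0], [0, 0, 0]]))
        m = metrics(cm, 2)
        assert m.undefined and m.recall == 0.0 and m.precision == 0.0

    def test_multiclass_accuracy_consistent_with_trace(self, rng):
        counts = rng.integers(0, 20, size=(3, 3))
        counts[0, 0] += 1  # nonzero total
        cm = ConfusionMatrix(counts)
        micro_tp = sum(cm.counts[i, i] for i in range(3))
        assert cm.accuracy() == pytest.approx(100.0 * micro_tp / cm.total)

    def test_row_sum_invariant_enforced(self):
        with pytest.raises(ValueError, match="non-negative"):
            ConfusionMatrix(np.array([[1, -1, 0], [0, 1, 0], [0, 0, 1]]))


class TestClassifierSpec:
    def test_configured_estimators(self):
        lda = ClassifierSpec("lda").build()
        assert isinstance(lda, LinearDiscriminantAnalysis) and lda.solver == "svd"
        svm = ClassifierSpec("linear_svm").build()
        assert isinstance(svm, SVC) and svm.kernel == "linear" and svm.C == 0.6
        assert svm.decision_function_shape == "ovo"
        rf = ClassifierSpec("random_forest").build()
        assert isinstance(rf, RandomForestClassifier)
        assert rf.n_estimators == 160 and rf.max_features == "sqrt" and rf.min_samples_leaf == 1

    def test_alternative_hyperparameters_exposed(self):
        assert ClassifierSpec("linear_svm", svm_c=1.0).build().C == 1.0
        assert ClassifierSpec("random_forest", rf_n_trees=10).build().n_estimators == 10

    @pytest.mark.parametrize("kwargs", [dict(kind="knn"), dict(kind="lda", svm_c=-1),
                                        dict(kind="random_forest", rf_n_trees=0)])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ClassifierSpec(**kwargs)
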