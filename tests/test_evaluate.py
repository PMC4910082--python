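import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histotex.classify import ClassifierSpec
from histotex.evaluate import (
    confusion_matrix,
    cross_validate,
    kfold_split,
    roc_one_vs_all,
    run_benchmark,
)


class TestKfoldSplit:
    def test_balanced_fold_sizes(self):
        folds = kfold_split(5000, 10, seed=0)
        counts = np.bincount(folds)
        assert len(counts) == 10
        assert np.all(counts == 500)

    def test_leave_one_out_limit(self):
        folds = kfold_split(10, 10, seed=1)
        assert sorted(folds) == list(range(10))

    def test_deterministic_under_seed(self):
        assert np.array_equal(kfold_split(101, 10, 42),
                              kfold_split(101, 10, 42))

    def test_more_folds_than_samples_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(5, 10, 0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(n=st.integers(10, 300), k=st.integers(2, 10),
           seed=st.integers(0, 1000))
    def test_partition_property(self, n, k, seed):
        folds = kfold_split(n, k, seed)
        counts = np.bincount(folds, minlength=k)
        assert folds.shape == (n,)
        assert counts.sum() == n
        assert counts.max() - counts.min() <= 1


class TestCrossValidate:
    def test_separable_data_perfect_accuracy(self, separable_clusters):
        X, y = separable_clusters
        res = cross_validate(X, y, ClassifierSpec("nn1"), k=10, seed=0)
        assert res.mean_accuracy == 1.0
        assert np.allclose(res.fold_accuracies, 1.0)

    def test_permuted_labels_give_chance_level(self, separable_clusters):
        X, y = separable_clusters
        y_perm = np.random.default_rng(5).permutation(y)
        res = cross_validate(X, y_perm, ClassifierSpec("nn1"), k=10, seed=0)
        assert 0.4 <= res.mean_accuracy <= 0.6

    def test_confusion_conserves_sample_count(self, separable_clusters):
        X, y = separable_clusters
        res = cross_validate(X, y, ClassifierSpec("rbf_svm"), k=5, seed=1)
        assert res.pooled_confusion.sum() == len(y)
        # confusion rows = per-class counts
        assert np.array_equal(res.pooled_confusion.sum(axis=1),
                              np.bincount(y)[1:])

    def test_every_sample_tested_once(self, separable_clusters):
        X, y = separable_clusters
        res = cross_validate(X, y, ClassifierSpec("nn1"), k=10, seed=2)
        counts = np.bincount(res.fold_assignment)
        assert counts.sum() == len(y)
        assert np.all(res.pooled_scores.sum(axis=1) > 0.99)

    def test_repeated_cv_concatenates_runs(self, separable_clusters):
        X, y = separable_clusters
        res = cross_validate(X, y, ClassifierSpec("nn1"), k=5, seed=0,
                             repeats=3)
        assert res.fold_accuracies.shape == (15,)
        assert res.pooled_confusion.sum() == 3 * len(y)
        assert np.allclose(res.pooled_scores.sum(axis=1), 1.0)

    def test_pooled_accuracy_consistent_with_folds(self, separable_clusters):
        X, y = separable_clusters
        res = cross_validate(X, y, ClassifierSpec("rusboost", seed=0),
                             k=10, seed=3)
        pooled_acc = np.trace(res.pooled_confusion) / len(y)
        fold_sizes = np.bincount(res.fold_assignment)
        weighted = np.sum(res.fold_accuracies * fold_sizes) / len(y)
        assert np.isclose(pooled_acc, weighted)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array([1, 1, 2, 3, 3, 3])
        cm = confusion_matrix(y, y, 3)
        assert np.array_equal(cm, np.diag([2, 1, 3]))

    def test_hand_enumerated_example(self):
        cm = confusion_matrix([1, 1, 2], [1, 2, 2], 2)
        assert np.array_equal(cm, [[1, 1], [0, 1]])

    def test_total_is_sample_count(self, rng):
        y_true = rng.integers(1, 5, 50)
        y_pred = rng.integers(1, 5, 50)
        assert confusion_matrix(y_true, y_pred, 4).sum() == 50

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([1, 5], [1, 1], 4)


class TestRocOneVsAll:
    def test_one_hot_scores_give_unit_auc(self):
        y = np.array([1, 1, 2, 2, 3, 3])
        scores = np.eye(3)[y - 1]
        out = roc_one_vs_all(scores, y)
        assert all(np.isclose(a, 1.0) for a in out["aucs"].values())
        assert np.isclose(out["mean_auc"], 1.0)

    def test_reversed_scores_give_zero_auc(self):
        y = np.array([1, 1, 2, 2])
        scores = 1.0 - np.eye(2)[y - 1]
        out = roc_one_vs_all(scores, y)
        assert all(np.isclose(a, 0.0) for a in out["aucs"].values())

    def test_random_scores_are_chance_level(self):
        rng = np.random.default_rng(0)
        n = 2000
        y = np.repeat([1, 2], n // 2)
        raw = rng.random((n, 2))
        scores = raw / raw.sum(axis=1, keepdims=True)
        out = roc_one_vs_all(scores, y)
        assert 0.45 <= out["mean_auc"] <= 0.55

    def test_absent_class_skipped_with_warning(self):
        y = np.array([1, 1, 1, 2])
        scores = np.full((4, 3), 1 / 3)
        with pytest.warns(UserWarning, match="class 3"):
            out = roc_one_vs_all(scores, y)
        assert 3 not in out["aucs"]


class TestRunBenchmark:
    def test_single_cell_grid(self, small_dataset):
        table = run_benchmark(
            small_dataset, ["histogram_lower"],
            [ClassifierSpec("nn1")], problems=("multi_class",),
            k=5, seed=0,
        )
        assert len(table) == 1
        assert np.isclose(
            table["error_rate"][0], 1 - table["mean_accuracy"][0]
        )

    def test_two_class_restricts_to_named_classes(self, small_dataset):
        table = run_benchmark(
            small_dataset, ["histogram_lower"],
            [ClassifierSpec("nn1")], problems=("two_class",),
            k=5, seed=0,
        )
        assert len(table) == 1

    def test_rerun_same_seed_is_identical(self, small_dataset):
        kwargs = dict(
            feature_sets=["glcm"],
            classifier_specs=[ClassifierSpec("rusboost", seed=4)],
            problems=("multi_class",), k=5, seed=4,
        )
        a = run_benchmark(small_dataset, **kwargs)
        b = run_benchmark(small_dataset, **kwargs)
        assert a.equals(b)

    def test_combined_set_at_least_matches_weakest_pure_set(
        self, small_dataset
    ):
        # mirror of the published ranking: the combined best5 set should
        # not do worse than histogram-lower alone; soft property — a
        # violation warns rather than fails
        import warnings

        table = run_benchmark(
            small_dataset, ["histogram_lower", "best5"],
            [ClassifierSpec("rbf_svm")], problems=("multi_class",),
            k=5, seed=0,
        )
        acc = table.set_index("feature_set")["mean_accuracy"]
        if acc["best5"] < acc["histogram_lower"]:
            warnings.warn(
                "best5 underperformed histogram_lower on the fixture set"
            )
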