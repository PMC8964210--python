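"""Metrics, splits, cross-validation, and the comparison experiment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score, precision_recall_fscore_support

from cytoswarm.evaluation import (
    ConfusionMatrix,
    ExperimentConfig,
    binary_metrics,
    collapse_to_binary,
    confusion_matrix,
    evaluate_predictions,
    kappa,
    kfold_cv,
    mse_metric,
    prf,
    run_experiment,
    stratified_split,
)
from cytoswarm.fcm import FCMConfig
from cytoswarm.qgh import SwarmConfig
from cytoswarm.synthetic import CLASS_NAMES, planted_feature_groups

TABLE6 = ConfusionMatrix(np.array([[482, 30], [6, 382]]), ("cancerous", "normal"))


class TestConfusionMatrix:
    def test_hand_count(self):
        cm = confusion_matrix(["A", "A", "B"], ["A", "B", "B"], ["A", "B"])
        assert cm.counts.tolist() == [[1, 1], [0, 1]]

    def test_perfect_predictions_diagonal(self):
        y = ["a", "b", "c", "a"]
        cm = confusion_matrix(y, y, ["a", "b", "c"])
        assert np.array_equal(cm.counts, np.diag([2, 1, 1]))

    def test_empty_inputs_zero_matrix(self):
        cm = confusion_matrix([], [], ["a", "b"])
        assert cm.counts.sum() == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="y_pred"):
            confusion_matrix(["a"], ["z"], ["a", "b"])


class TestPRF:
    def test_hand_arithmetic_two_class(self):
        cm = ConfusionMatrix(np.array([[1, 1], [0, 1]]), ("A", "B"))
        scores = prf(cm)
        assert scores["per_class_precision"] == pytest.approx([1.0, 0.5])
        assert scores["per_class_recall"] == pytest.approx([0.5, 1.0])
        assert scores["per_class_f1"] == pytest.approx([2 / 3, 2 / 3])
        assert scores["macro_f1"] == pytest.approx(2 / 3)

    def test_diagonal_matrix_all_ones(self):
        scores = prf(ConfusionMatrix(np.diag([3, 4, 5]), ("a", "b", "c")))
        assert scores["macro_precision"] == scores["macro_recall"] == scores["macro_f1"] == 1.0

    def test_never_predicted_class_gets_zero_with_warning(self):
        cm = ConfusionMatrix(np.array([[2, 0], [1, 0]]), ("a", "b"))
        with pytest.warns(UserWarning, match="never predicted"):
            scores = prf(cm)
        assert scores["per_class_precision"][1] == 0.0
        assert scores["per_class_f1"][1] == 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_sklearn_on_random_labelings(self, seed):
        rng = np.random.default_rng(seed)
        classes = ["a", "b", "c"]
        y_true = rng.choice(classes, size=30)
        y_pred = rng.choice(classes, size=30)
        cm = confusion_matrix(y_true, y_pred, classes)
        scores = prf(cm, warn=False)
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, zero_division=0
        )
        assert scores["per_class_precision"] == pytest.approx(p)
        assert scores["per_class_recall"] == pytest.approx(r)
        assert scores["per_class_f1"] == pytest.approx(f)
        assert kappa(cm) == pytest.approx(
            cohen_kappa_score(y_true, y_pred, labels=classes)
        )


class TestBinaryMetrics:
    def test_published_confusion_cells(self):
        """The published 900-test-case binary confusion matrix (482/30/6/382)
        gives 0.96 correctly-classified and 0.04 error."""
        metrics = binary_metrics(TABLE6)
        assert metrics["accuracy"] == pytest.approx(0.96)
        assert metrics["error_rate"] == pytest.approx(0.04)
        assert metrics["sensitivity"] == pytest.approx(482 / 512)
        assert metrics["specificity"] == pytest.approx(382 / 388)

    def test_degenerate_all_positive(self):
        cm = ConfusionMatrix(np.array([[5, 0], [0, 0]]), ("p", "n"))
        metrics = binary_metrics(cm)
        assert metrics["accuracy"] == 1.0 and metrics["sensitivity"] == 1.0
        assert metrics["specificity"] is None


class TestCollapse:
    def _diag7(self, value=10):
        return ConfusionMatrix(np.diag([value] * 7), CLASS_NAMES)

    def test_all_correct_collapses_to_diagonal(self):
        cm2 = collapse_to_binary(self._diag7())
        assert cm2.counts.tolist() == [[40, 0], [0, 30]]

    def test_within_cancerous_confusion_counts_as_true_positive(self):
        counts = np.diag([10] * 7)
        i = CLASS_NAMES.index("in_situ")
        j = CLASS_NAMES.index("last_stage_dysplastic")
        counts[i, i] = 0
        counts[i, j] = 10  # in_situ predicted as another cancerous grade
        cm2 = collapse_to_binary(ConfusionMatrix(counts, CLASS_NAMES))
        assert cm2.counts[0, 0] == 40  # still all true positives

    def test_totals_preserved(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(7, 7))
        cm = ConfusionMatrix(counts, CLASS_NAMES)
        assert collapse_to_binary(cm).total == cm.total

    def test_unknown_class_rejected(self):
        cm = ConfusionMatrix(np.diag([1, 1]), ("a", "b"))
        with pytest.raises(ValueError, match="unknown"):
            collapse_to_binary(cm)


class TestKappa:
    def test_perfect_agreement(self):
        assert kappa(ConfusionMatrix(np.diag([5, 5]), ("a", "b"))) == 1.0

    def test_constant_prediction_balanced_truth_is_zero(self):
        cm = ConfusionMatrix(np.array([[10, 0], [10, 0]]), ("a", "b"))
        assert kappa(cm) == pytest.approx(0.0)

    def test_published_cells_value(self):
        # standard Cohen's kappa of the published binary confusion cells
        assert kappa(TABLE6) == pytest.approx(0.919, abs=5e-4)

    def test_chance_agreement_one_defined_as_zero(self):
        cm = ConfusionMatrix(np.array([[5, 0], [0, 0]]), ("a", "b"))
        with pytest.warns(UserWarning, match="chance agreement"):
            assert kappa(cm) == 0.0


class TestMSE:
    def test_one_hot_correct_is_zero(self):
        U = np.eye(2)[[0, 1, 0]]
        assert mse_metric(U, ["a", "b", "a"], ["a", "b"]) == 0.0

    def test_one_hot_always_wrong_two_classes(self):
        U = np.eye(2)[[1, 0]]
        assert mse_metric(U, ["a", "b"], ["a", "b"]) == 1.0

    def test_uniform_memberships_two_classes(self):
        U = np.full((4, 2), 0.5)
        assert mse_metric(U, ["a", "b", "a", "b"], ["a", "b"]) == pytest.approx(0.25)


class TestSplits:
    def test_balanced_70_30(self):
        labels = np.array(["a"] * 50 + ["b"] * 50)
        train, test = stratified_split(labels, 0.3, seed=0)
        assert train.size == 70 and test.size == 30
        assert (labels[test] == "a").sum() == 15

    def test_seeded_and_exhaustive(self):
        labels = np.array(["a"] * 20 + ["b"] * 30 + ["c"] * 10)
        a = stratified_split(labels, 0.3, seed=4)
        b = stratified_split(labels, 0.3, seed=4)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        union = np.concatenate(a)
        assert np.array_equal(np.sort(union), np.arange(60))

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            stratified_split(np.array(["a", "a", "b"]), 0.3, seed=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_split_proportions_property(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(4, 20, size=3)
        labels = np.repeat(["a", "b", "c"], counts)
        train, test = stratified_split(labels, 0.3, seed=seed)
        assert np.intersect1d(train, test).size == 0
        assert train.size + test.size == labels.size
        for c, n in zip(["a", "b", "c"], counts):
            expected = 0.3 * n
            got = (labels[test] == c).sum()
            assert abs(got - expected) <= 1


class TestKFold:
    def test_fold_sizes_and_partition(self):
        gf, labels, _ = planted_feature_groups(n_per_class=12, n_classes=4, seed=0)
        reports, summary = kfold_cv(
            gf.X, labels, FCMConfig(n_clusters=4, seed=0, n_init=1, max_iter=50), k=12, seed=1
        )
        assert summary["k"] == 12
        sizes = [r.confusion.total for r in reports]
        assert sizes == [4] * 12
        assert sum(sizes) == labels.size
        macro = [r.macro_f1 for r in reports]
        assert summary["macro_f1_mean"] == pytest.approx(np.mean(macro))

    def test_k_reduced_when_class_too_rare(self):
        gf, labels, _ = planted_feature_groups(n_per_class=5, n_classes=3, seed=0)
        with pytest.warns(UserWarning, match="reducing k"):
            _, summary = kfold_cv(
                gf.X, labels, FCMConfig(n_clusters=3, seed=0, n_init=1, max_iter=40), k=12, seed=0
            )
        assert summary["k"] == 5

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError, match="12-fold"):
            kfold_cv(np.zeros((5, 2)), np.array(["a", "b", "a", "b", "a"]), k=12)


@pytest.fixture(scope="module")
def planted_experiment():
    gf, labels, informative = planted_feature_groups(seed=5)
    config = ExperimentConfig(
        seed=5,
        fcm=FCMConfig(seed=5, n_init=2),
        fitness_fcm=FCMConfig(seed=5, n_init=1, max_iter=80),
        swarm=SwarmConfig(seed=5, n_particles=10, n_iterations=12),
        knn_baseline=True,
    )
    return run_experiment(gf, labels, config), informative


class TestExperiment:
    def test_report_schema(self, planted_experiment):
        report, _ = planted_experiment
        assert report["without_selection"]["confusion"] is not None
        assert report["with_selection"]["confusion"] is not None
        assert len(report["selected_mask"]) == 14
        assert sum(report["selected_mask"]) >= 1
        assert report["n_train"] + report["n_test"] == 24 * 7
        assert "knn_baseline" in report

    def test_selection_not_much_worse_than_all_features(self, planted_experiment):
        report, _ = planted_experiment
        assert (
            report["with_selection"]["macro_f1"]
            >= report["without_selection"]["macro_f1"] - 0.05
        )

    def test_selection_disabled_marks_stage_absent(self):
        gf, labels, _ = planted_feature_groups(n_per_class=10, seed=1)
        config = ExperimentConfig(
            seed=1, selection=False, fcm=FCMConfig(seed=1, n_init=1, max_iter=50)
        )
        report = run_experiment(gf, labels, config)
        assert report["with_selection"] is None and report["selection"] is None

    def test_single_class_rejected(self):
        gf, labels, _ = planted_feature_groups(n_per_class=10, seed=1)
        with pytest.raises(ValueError, match="2 classes"):
            run_experiment(gf, np.array(["x"] * labels.size), ExperimentConfig())

    def test_binary_block_present_for_canonical_classes(self, small_dataset):
        from cytoswarm.features import feature_table, grouped_from_table

        cells, _ = small_dataset
        df = feature_table(cells)
        gf, labels = grouped_from_table(df)
        config = ExperimentConfig(
            seed=2, selection=False, fcm=FCMConfig(seed=2, n_init=2, max_iter=100)
        )
        report = run_experiment(gf, labels, config)
        binary = report["without_selection"]["binary"]
        assert set(binary) == {"accuracy", "error_rate", "sensitivity", "specificity", "precision"}
        assert report["class_names"] == list(CLASS_NAMES)
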