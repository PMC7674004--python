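"""Nested LOOCV harness: folds, selection, tuning, scoring."""

import numpy as np
import pandas as pd
import pytest

from octamls import (
    CohortEffectSpec,
    HyperparameterGrid,
    NestedCVResult,
    auroc,
    generate_cohort_feature_table,
    make_loocv_folds,
    rank_features_univariate,
    run_nested_evaluation,
    score_binary,
    score_multiclass,
    tune_hyperparameters,
)
from octamls.core import feature_columns
from octamls.harness import task_labels

TINY = HyperparameterGrid.tiny()


def _shifted_cohort(n_per_group, shift_features, delta_sd=3.0, seed=0, sd=8.0):
    effect = {_split(f): -delta_sd * sd for f in shift_features}
    spec = CohortEffectSpec(n_per_group=n_per_group, effect_map=effect, vim_sd=sd, seed=seed)
    return generate_cohort_feature_table(spec)


def _split(name):
    layer, sector = name.rsplit("_", 1)
    return layer, sector


class TestLoocvFolds:
    def test_reference_cohort_size(self):
        assert len(make_loocv_folds([f"S{i}" for i in range(121)])) == 121

    def test_two_subjects(self):
        folds = make_loocv_folds(["a", "b"])
        assert len(folds) == 2
        assert all(len(te) == 1 for _, te in folds)

    def test_test_sets_partition_cohort(self):
        folds = make_loocv_folds(list(range(17)))
        tests = np.concatenate([te for _, te in folds])
        assert sorted(tests) == list(range(17))
        for tr, te in folds:
            assert set(tr) & set(te) == set()
            assert len(tr) + len(te) == 17

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            make_loocv_folds(["only"])


class TestRankFeatures:
    def test_shifted_feature_ranked_first_most_seeds(self):
        hits = 0
        for seed in range(30):
            t = _shifted_cohort({"control": 15, "glaucoma": 15}, ["superficial_IT"], seed=seed)
            y = task_labels(t, "diagnosis")
            ranked = rank_features_univariate(t, y, kind="binary")
            hits += ranked["feature"].iloc[0] == "superficial_IT"
        assert hits >= 28

    def test_k_equals_42_returns_all(self, small_cohort):
        y = task_labels(small_cohort, "diagnosis")
        ranked = rank_features_univariate(small_cohort, y, kind="binary")
        assert len(ranked) == 42
        assert set(ranked["feature"]) == set(feature_columns())

    def test_duplicated_columns_adjacent_in_canonical_order(self, small_cohort):
        t = small_cohort.copy()
        t["deep_ST"] = t["superficial_ST"]  # duplicate an earlier column
        y = task_labels(t, "diagnosis")
        ranked = rank_features_univariate(t, y, kind="binary")
        pos = {f: i for i, f in enumerate(ranked["feature"])}
        assert abs(pos["superficial_ST"] - pos["deep_ST"]) == 1
        assert pos["superficial_ST"] < pos["deep_ST"]  # canonical tie-break

    def test_constant_feature_ranked_last_with_p_one(self, small_cohort):
        t = small_cohort.copy()
        t["choroid_CP"] = 50.0
        y = task_labels(t, "diagnosis")
        ranked = rank_features_univariate(t, y, kind="binary")
        last = ranked.iloc[-1]
        assert last["feature"] == "choroid_CP" and last["p_value"] == 1.0

    def test_multiclass_uses_kruskal_wallis(self):
        t = _shifted_cohort(
            {"healthy": 8, "mild": 8, "moderate": 8, "severe": 8}, ["superficial_IT"]
        )
        y = task_labels(t, "severity")
        ranked = rank_features_univariate(t, y, kind="multiclass")
        assert ranked["feature"].iloc[0] == "superficial_IT"


class TestTuneHyperparameters:
    def test_single_configuration_returned(self, rng):
        X = rng.normal(0, 1, (30, 3))
        y = np.repeat([0, 1], 15)
        grid = HyperparameterGrid(svm=[{"kernel": ["linear"], "C": [1.0]}])
        _, params, _ = tune_hyperparameters(X, y, "svm", grid, seed=0)
        assert params == {"kernel": "linear", "C": 1.0}

    @pytest.mark.parametrize("C", [1.0, 10.0, 100.0])
    def test_separable_data_inner_accuracy_one(self, C, rng):
        X = np.concatenate([rng.normal(-5, 0.3, (20, 2)), rng.normal(5, 0.3, (20, 2))])
        y = np.repeat([0, 1], 20)
        grid = HyperparameterGrid(svm=[{"kernel": ["linear"], "C": [C]}])
        _, _, acc = tune_hyperparameters(X, y, "svm", grid, seed=0)
        assert acc == 1.0

    def test_same_seed_same_choice(self, rng):
        X = rng.normal(0, 1, (40, 4))
        y = np.repeat([0, 1], 20)
        grid = HyperparameterGrid(rf={"n_estimators": [10, 25], "max_depth": [2, None]})
        _, p1, a1 = tune_hyperparameters(X, y, "rf", grid, seed=7)
        _, p2, a2 = tune_hyperparameters(X, y, "rf", grid, seed=7)
        assert p1 == p2 and a1 == a2

    def test_small_class_degrades_folds_with_warning(self, rng):
        X = rng.normal(0, 1, (13, 3))
        y = np.array([0] * 10 + [1] * 3)
        grid = HyperparameterGrid(svm=[{"kernel": ["linear"], "C": [1.0]}])
        with pytest.warns(UserWarning, match="inner folds"):
            tune_hyperparameters(X, y, "svm", grid, seed=0)


class TestNestedEvaluation:
    def test_accuracy_vs_k_curve_has_42_points(self):
        t = _shifted_cohort({"control": 8, "glaucoma": 8}, ["superficial_IT"])
        res = run_nested_evaluation(
            t, "diagnosis", model="svm", grid=TINY, feature_set="selected", seed=0
        )
        assert len(res.accuracy_by_k) == 42
        assert res.chosen_k == min(
            k for k, a in res.accuracy_by_k.items()
            if a == max(res.accuracy_by_k.values())
        )

    def test_every_subject_predicted_once(self, small_cohort):
        res = run_nested_evaluation(
            small_cohort, "diagnosis", model="svm", grid=TINY, feature_set="all", seed=0
        )
        assert len(res.predictions) == len(small_cohort)
        assert len(res.per_fold) == len(small_cohort)

    def test_no_leakage_poisoned_test_subject(self):
        """Corrupting one subject's features must not change the artifacts
        of folds where that subject is in the test position's training data
        complement — i.e. fold i's training artifacts ignore subject i."""
        t = _shifted_cohort({"control": 7, "glaucoma": 7}, ["superficial_IT"], seed=4)
        res_clean = run_nested_evaluation(
            t, "diagnosis", model="svm", grid=TINY, feature_set="all", seed=0
        )
        poisoned = t.copy()
        poisoned.loc[poisoned.index[0], feature_columns()] = 999.0
        res_poisoned = run_nested_evaluation(
            poisoned, "diagnosis", model="svm", grid=TINY, feature_set="all", seed=0
        )
        assert res_clean.per_fold[0]["params"] == res_poisoned.per_fold[0]["params"]
        assert res_clean.per_fold[0]["inner_accuracy"] == pytest.approx(
            res_poisoned.per_fold[0]["inner_accuracy"]
        )

    def test_perfectly_separating_single_feature_auroc_one(self):
        t = _shifted_cohort({"control": 10, "glaucoma": 10}, [], seed=1)
        labels = task_labels(t, "diagnosis")
        t["superficial_IT"] = np.where(labels == "glaucoma", 10.0, 200.0)
        res = run_nested_evaluation(
            t, "diagnosis", model="svm", grid=TINY, feature_set="superficial_IT", seed=0
        )
        y_bin = res.y_true == "glaucoma"
        assert auroc(res.scores, y_bin) == 1.0

    def test_rnfl_single_feature_baseline_runs(self, small_cohort):
        res = run_nested_evaluation(
            small_cohort, "diagnosis", model="svm", grid=TINY, feature_set="rnfl_um", seed=0
        )
        assert auroc(res.scores, res.y_true == "glaucoma") > 0.7

    def test_unknown_feature_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="unknown feature"):
            run_nested_evaluation(small_cohort, "diagnosis", feature_set="nope", seed=0)

    def test_auroc_monotone_in_effect_size(self):
        """Outer AUROC non-decreasing over 0/1/2/3 SD (one inversion allowed)."""
        aurocs = []
        for delta in (0.0, 1.0, 2.0, 3.0):
            t = _shifted_cohort(
                {"control": 20, "glaucoma": 20},
                ["superficial_IT", "superficial_CP", "deep_IT"],
                delta_sd=delta,
                seed=12,
            )
            res = run_nested_evaluation(
                t, "diagnosis", model="svm", grid=TINY, feature_set="all", seed=0
            )
            aurocs.append(auroc(res.scores, res.y_true == "glaucoma"))
        inversions = sum(b < a - 1e-9 for a, b in zip(aurocs, aurocs[1:]))
        assert inversions <= 1
        assert aurocs[-1] > aurocs[0]

    @pytest.mark.parametrize("model", ["rf", "xgb"])
    def test_tree_models_run(self, model):
        t = _shifted_cohort({"control": 8, "glaucoma": 8}, ["superficial_IT"], seed=2)
        res = run_nested_evaluation(
            t, "diagnosis", model=model, grid=TINY, feature_set="all", seed=0
        )
        assert set(res.predictions) <= {"control", "glaucoma"}

    def test_severity_one_vs_all_scores_shape(self):
        t = _shifted_cohort(
            {"healthy": 6, "mild": 6, "moderate": 6, "severe": 6}, ["superficial_IT"],
            delta_sd=2.0, seed=3,
        )
        res = run_nested_evaluation(
            t, "severity", model="svm", grid=TINY, feature_set="all", seed=0
        )
        assert res.scores.shape == (24, 4)
        assert res.classes == ["healthy", "mild", "moderate", "severe"]


class TestScoring:
    def _result(self, y, preds, scores, classes, task="severity"):
        return NestedCVResult(
            task=task,
            model="svm",
            feature_set="all",
            classes=classes,
            subject_ids=[str(i) for i in range(len(y))],
            y_true=np.asarray(y),
            predictions=np.asarray(preds),
            scores=np.asarray(scores),
        )

    def test_perfect_predictions_all_metrics_one(self):
        classes = ["healthy", "mild", "moderate", "severe"]
        y = np.repeat(classes, 10)
        scores = np.zeros((40, 4))
        for i, c in enumerate(y):
            scores[i, classes.index(c)] = 1.0
        report = score_multiclass(self._result(y, y, scores, classes), n_boot=200)
        for name in ("auroc", "accuracy", "sensitivity", "specificity"):
            assert report.metrics[name][0] == 1.0
        assert np.all(report.confusion_matrix == np.diag([10] * 4))

    def test_random_predictions_quarter_accuracy(self):
        """Uniform guessing on a balanced 4-class cohort scores ~0.25.

        A single 400-draw accuracy has sd ~0.022, so the check averages
        over fixed replicate seeds to measure the expectation at the
        stated +/-0.03 tolerance without widening it.
        """
        classes = ["healthy", "mild", "moderate", "severe"]
        y = np.repeat(classes, 100)
        accs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            preds = r.choice(classes, 400)
            scores = r.uniform(0, 1, (400, 4))
            report = score_multiclass(self._result(y, preds, scores, classes), n_boot=50)
            accs.append(report.metrics["accuracy"][0])
        assert np.mean(accs) == pytest.approx(0.25, abs=0.03)

    def test_micro_sensitivity_equals_accuracy(self):
        classes = ["a", "b", "c"]
        r = np.random.default_rng(5)
        for _ in range(10):
            y = r.choice(classes, 30)
            if len(set(y)) < 3:
                continue
            preds = r.choice(classes, 30)
            scores = r.uniform(0, 1, (30, 3))
            rep = score_multiclass(self._result(y, preds, scores, classes), n_boot=50)
            assert rep.metrics["sensitivity"][0] == pytest.approx(rep.metrics["accuracy"][0])

    def test_confusion_matrix_row_sums_are_class_counts(self):
        classes = ["healthy", "mild", "moderate", "severe"]
        r = np.random.default_rng(2)
        y = np.repeat(classes, [10, 7, 6, 5])
        preds = r.choice(classes, len(y))
        scores = r.uniform(0, 1, (len(y), 4))
        rep = score_multiclass(self._result(y, preds, scores, classes), n_boot=50)
        assert rep.confusion_matrix.sum(axis=1).tolist() == [10, 7, 6, 5]

    def test_binary_report_ci_brackets_point(self, small_cohort):
        res = run_nested_evaluation(
            small_cohort, "diagnosis", model="svm", grid=TINY, feature_set="all", seed=0
        )
        rep = score_binary(res, n_boot=500, seed=0)
        for point, lo, hi in rep.metrics.values():
            assert lo <= point + 1e-9 and point - 1e-9 <= hi
            assert 0.0 <= lo <= hi <= 1.0

    def test_missing_predicted_class_warns(self):
        classes = ["healthy", "mild", "moderate", "severe"]
        y = np.repeat(classes, 5)
        preds = np.repeat("healthy", 20)
        scores = np.random.default_rng(0).uniform(0, 1, (20, 4))
        with pytest.warns(UserWarning, match="never predicted"):
            score_multiclass(self._result(y, preds, scores, classes), n_boot=50)
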