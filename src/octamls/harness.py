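"""Nested leave-one-out evaluation of the multi-layer/multi-sector models.

Three tasks are supported on the 42-feature VIM table: ``diagnosis``
(control vs glaucoma), ``type`` (POAG vs NTG) and ``severity`` (four
levels, one-vs-all).  The outer loop is leave-one-out over subjects; inside
each outer training split, features are ranked by univariate p-value
(Mann-Whitney for binary tasks, Kruskal-Wallis for the multiclass task)
and hyperparameters are tuned by exhaustive grid search under stratified
5-fold cross-validation.  The number of selected features k is chosen as
the argmax of the *outer* accuracy-vs-k curve — exactly the published
protocol, which is optimistically biased and flagged as such in reports.

With the full default grids and all 42 values of k this is an expensive
computation; pass a reduced ``grid`` and/or ``k_grid`` for desk-scale runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import SEVERITY_LEVELS, feature_columns
from .stats import auroc, kruskal_wallis, mann_whitney, stratified_bootstrap_ci

TASKS = ("diagnosis", "type", "severity")
MODELS = ("svm", "rf", "xgb")

_DECADES = [1e-5, 1e-4, 1e-3, 1e-2, 0.1, 1.0, 10.0, 100.0, 1000.0]


@dataclass(frozen=True)
class HyperparameterGrid:
    """Grid-search spaces per model, in scikit-learn ``param_grid`` form.

    The gradient-boosting grid maps the usual boosted-tree knobs onto
    ``GradientBoostingClassifier``: minimum loss reduction (gamma) ->
    ``min_impurity_decrease``, column subsampling -> ``max_features``,
    leaf-size percentage -> fractional ``min_samples_leaf`` (scikit-learn
    converts fractions to counts by ceiling).
    """

    svm: list[dict] = field(
        default_factory=lambda: [
            {"kernel": ["linear"], "C": list(_DECADES)},
            {"kernel": ["rbf"], "C": list(_DECADES), "gamma": list(_DECADES)},
        ]
    )
    rf: dict = field(
        default_factory=lambda: {
            "n_estimators": [10, 25, 50],
            "criterion": ["gini", "entropy"],
            "bootstrap": [True, False],
            "min_samples_leaf": [0.1, 0.3, 0.5],
            "min_samples_split": [0.1, 0.3, 0.5],
            "max_depth": [5, 10, 15, None],
        }
    )
    xgb: dict = field(
        default_factory=lambda: {
            "learning_rate": [0.01, 0.1, 0.25],
            "min_impurity_decrease": [0.1, 1.0, 3.0],
            "subsample": [0.6, 0.8, 1.0],
            "max_features": [0.6, 0.8, 1.0],
            "min_samples_leaf": [0.1, 0.3, 0.5],
            "max_depth": [5, 10, 15, None],
        }
    )

    def for_model(self, model: str):
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
        return getattr(self, model)

    @classmethod
    def tiny(cls, model: str = "svm") -> "HyperparameterGrid":
        """A desk-scale grid (a few configurations) for tests and demos."""
        return cls(
            svm=[{"kernel": ["linear"], "C": [0.1, 1.0, 10.0]}],
            rf={"n_estimators": [25], "max_depth": [5, None]},
            xgb={"learning_rate": [0.1], "max_depth": [3]},
        )


@dataclass
class NestedCVResult:
    """Per-subject out-of-fold predictions and the selection trail."""

    task: str
    model: str
    feature_set: str
    classes: list[str]
    subject_ids: list[str]
    y_true: np.ndarray
    predictions: np.ndarray
    scores: np.ndarray  # (n,) binary decision scores or (n, k) one-vs-all
    accuracy_by_k: dict[int, float] | None = None
    chosen_k: int | None = None
    per_fold: list[dict] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.predictions == self.y_true))


@dataclass
class MetricsReport:
    """Point estimates with 95% stratified-bootstrap CIs.

    ``metrics`` maps a metric name to ``(point, ci_low, ci_high)``.  For
    multiclass results the metrics are micro-averaged over the pooled
    one-vs-all binarization, where micro-sensitivity equals accuracy.
    """

    task: str
    model: str
    metrics: dict[str, tuple[float, float, float]]
    confusion_matrix: np.ndarray | None = None
    classes: list[str] | None = None
    note: str = ""


def make_loocv_folds(subject_ids) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-out fold plan: fold i tests subject i, trains on the rest."""
    n = len(subject_ids)
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 subjects")
    idx = np.arange(n)
    return [(np.delete(idx, i), np.array([i])) for i in range(n)]


def task_labels(table: pd.DataFrame, task: str) -> np.ndarray:
    """Map the table's ``label`` column onto the task's class vocabulary."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    raw = table["label"].astype(str)
    if task == "diagnosis":
        control = {"control", "healthy"}
        return np.where(raw.isin(control), "control", "glaucoma")
    if task == "type":
        bad = set(raw.unique()) - {"POAG", "NTG"}
        if bad:
            raise ValueError(f"type task needs POAG/NTG labels, got extra {bad}")
        return raw.to_numpy()
    mapped = raw.replace({"control": "healthy"})
    bad = set(mapped.unique()) - set(SEVERITY_LEVELS)
    if bad:
        raise ValueError(f"severity task needs {SEVERITY_LEVELS} labels, got extra {bad}")
    return mapped.to_numpy()


def task_classes(task: str) -> list[str]:
    if task == "diagnosis":
        return ["control", "glaucoma"]  # positive class last
    if task == "type":
        return ["NTG", "POAG"]
    return list(SEVERITY_LEVELS)


def rank_features_univariate(
    table: pd.DataFrame, y: np.ndarray, kind: str = "binary", features: list[str] | None = None
) -> pd.DataFrame:
    """Rank features by two-sided univariate p-value, ascending.

    Binary tasks use the Mann-Whitney test, multiclass the Kruskal-Wallis
    test.  A constant feature gets p = 1 and ranks last; ties in p are
    broken by the canonical layer-major, sector-minor feature order.
    """
    if features is None:
        features = [c for c in feature_columns() if c in table.columns]
    classes = np.unique(y)
    if kind == "binary" and len(classes) != 2:
        raise ValueError(f"binary ranking needs 2 classes, got {len(classes)}")
    records = []
    for canonical_idx, name in enumerate(features):
        col = table[name].to_numpy(dtype=float)
        groups = [col[y == c] for c in classes]
        if any(len(g) < 2 for g in groups):
            raise ValueError("need >= 2 samples per class to rank features")
        if kind == "binary":
            p = mann_whitney(groups[0], groups[1], mode="asymptotic").p_value
        else:
            p = kruskal_wallis(groups).p_value
        records.append((name, p, canonical_idx))
    records.sort(key=lambda r: (r[1], r[2]))
    return pd.DataFrame(records, columns=["feature", "p_value", "canonical_index"])


def _base_estimator(model: str, seed: int) -> tuple[object, str]:
    """Estimator plus the param-grid key prefix it needs.

    The SVM gets per-fold feature standardization (fit on the training
    split only, via a Pipeline, so nothing leaks); tree ensembles are
    scale-invariant and run on raw features.
    """
    if model == "svm":
        est = Pipeline(
            [("scale", StandardScaler()), ("clf", SVC(random_state=seed))]
        )
        return est, "clf__"
    if model == "rf":
        return RandomForestClassifier(random_state=seed), ""
    if model == "xgb":
        return GradientBoostingClassifier(random_state=seed), ""
    raise ValueError(f"unknown model {model!r}")


def _scores_of(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X))
    proba = np.asarray(est.predict_proba(X))
    return proba[:, 1] if proba.shape[1] == 2 else proba


def tune_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    model: str,
    grid: HyperparameterGrid | None = None,
    seed: int = 0,
    n_splits: int = 5,
    one_vs_all: bool = False,
):
    """Exhaustive grid search scored by stratified k-fold accuracy.

    Returns ``(fitted_estimator, best_params, inner_accuracy)``; the best
    configuration is refit on the full training split.  If the smallest
    class has fewer than ``n_splits`` members the fold count degrades
    gracefully (with a warning); below 2 members per class, unstratified
    folds are used.
    """
    grid = grid or HyperparameterGrid()
    param_grid = grid.for_model(model)
    base, prefix = _base_estimator(model, seed)
    if one_vs_all:
        base = OneVsRestClassifier(base)
        prefix = f"estimator__{prefix}"
    if prefix:
        if isinstance(param_grid, list):
            param_grid = [{f"{prefix}{k}": v for k, v in g.items()} for g in param_grid]
        else:
            param_grid = {f"{prefix}{k}": v for k, v in param_grid.items()}
    _, counts = np.unique(y, return_counts=True)
    min_count = int(counts.min())
    if min_count >= 2:
        eff = min(n_splits, min_count)
        if eff < n_splits:
            warnings.warn(
                f"smallest class has {min_count} members; using {eff} inner folds",
                stacklevel=2,
            )
        cv = StratifiedKFold(n_splits=eff)
    else:
        warnings.warn("a class has < 2 members; inner folds are unstratified", stacklevel=2)
        cv = KFold(n_splits=2)
    search = GridSearchCV(base, param_grid, scoring="accuracy", cv=cv, refit=True)
    search.fit(X, y)
    best_params = {k.removeprefix(prefix): v for k, v in search.best_params_.items()}
    return search.best_estimator_, best_params, float(search.best_score_)


def run_nested_evaluation(
    table: pd.DataFrame,
    task: str,
    model: str = "svm",
    grid: HyperparameterGrid | None = None,
    feature_set: str = "selected",
    k_grid: list[int] | None = None,
    seed: int = 0,
) -> NestedCVResult:
    """Outer leave-one-out evaluation with inner selection and tuning.

    ``feature_set`` is ``'all'``, ``'selected'`` (univariate top-k with the
    outer accuracy-vs-k curve deciding k; ties go to the smallest k), or a
    single feature name (e.g. ``'superficial_IT'`` or ``'rnfl_um'``) for
    the single-feature baselines.
    """
    grid = grid or HyperparameterGrid()
    y = task_labels(table, task)
    classes = task_classes(task)
    one_vs_all = task == "severity"
    vim_cols = [c for c in feature_columns() if c in table.columns]
    if feature_set in ("all", "selected"):
        candidate_features = vim_cols
    else:
        if feature_set not in table.columns:
            raise ValueError(f"unknown feature {feature_set!r}")
        candidate_features = [feature_set]
    folds = make_loocv_folds(table.index.to_list())
    n = len(folds)
    subject_ids = table["subject_id"].astype(str).to_list() if "subject_id" in table else [
        str(i) for i in range(n)
    ]

    def child_seed(tag: int) -> int:
        return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % 2**31)

    if feature_set != "selected":
        X = table[candidate_features].to_numpy(dtype=float)
        preds, scores, per_fold = [], [], []
        for i, (tr, te) in enumerate(folds):
            est, params, inner_acc = tune_hyperparameters(
                X[tr], y[tr], model, grid, seed=child_seed(i), one_vs_all=one_vs_all
            )
            pred = est.predict(X[te])[0]
            sc = _scores_of(est, X[te])
            if one_vs_all:
                order = [list(est.classes_).index(c) for c in classes]
                sc = sc[:, order]
            preds.append(pred)
            scores.append(sc[0])
            per_fold.append(
                {"features": candidate_features, "params": params, "inner_accuracy": inner_acc}
            )
        return NestedCVResult(
            task=task,
            model=model,
            feature_set=feature_set,
            classes=classes,
            subject_ids=subject_ids,
            y_true=y,
            predictions=np.asarray(preds),
            scores=np.asarray(scores),
            per_fold=per_fold,
        )

    # feature_set == "selected": per-k outer accuracy curve, then argmax k.
    k_values = k_grid if k_grid is not None else list(range(1, len(candidate_features) + 1))
    kind = "multiclass" if one_vs_all else "binary"
    preds_by_k = {k: [None] * n for k in k_values}
    scores_by_k = {k: [None] * n for k in k_values}
    fold_info: list[dict] = [dict() for _ in range(n)]
    for i, (tr, te) in enumerate(folds):
        ranked = rank_features_univariate(table.iloc[tr], y[tr], kind=kind, features=candidate_features)
        fold_info[i]["ranking"] = ranked["feature"].to_list()
        for k in k_values:
            feats = ranked["feature"].to_list()[:k]
            X_tr = table.iloc[tr][feats].to_numpy(dtype=float)
            X_te = table.iloc[te][feats].to_numpy(dtype=float)
            est, params, inner_acc = tune_hyperparameters(
                X_tr, y[tr], model, grid, seed=child_seed(i), one_vs_all=one_vs_all
            )
            pred = est.predict(X_te)[0]
            sc = _scores_of(est, X_te)
            if one_vs_all:
                order = [list(est.classes_).index(c) for c in classes]
                sc = sc[:, order]
            preds_by_k[k][i] = pred
            scores_by_k[k][i] = sc[0]
            fold_info[i][k] = {"features": feats, "params": params, "inner_accuracy": inner_acc}
    accuracy_by_k = {
        k: float(np.mean(np.asarray(preds_by_k[k]) == y)) for k in k_values
    }
    best_acc = max(accuracy_by_k.values())
    chosen_k = min(k for k, a in accuracy_by_k.items() if a == best_acc)
    per_fold = [
        {
            "selected_features": fold_info[i][chosen_k]["features"],
            "params": fold_info[i][chosen_k]["params"],
            "inner_accuracy": fold_info[i][chosen_k]["inner_accuracy"],
        }
        for i in range(n)
    ]
    return NestedCVResult(
        task=task,
        model=model,
        feature_set="selected",
        classes=classes,
        subject_ids=subject_ids,
        y_true=y,
        predictions=np.asarray(preds_by_k[chosen_k]),
        scores=np.asarray(scores_by_k[chosen_k]),
        accuracy_by_k=accuracy_by_k,
        chosen_k=chosen_k,
        per_fold=per_fold,
    )


def _binary_metric_fns(positive: str, negative: str):
    def acc(labels, preds):
        return float(np.mean(preds == labels))

    def sens(labels, preds):
        pos = labels == positive
        return float(np.mean(preds[pos] == positive))

    def spec(labels, preds):
        neg = labels == negative
        return float(np.mean(preds[neg] == negative))

    return acc, sens, spec


def score_binary(
    result: NestedCVResult, n_boot: int = 1000, seed: int = 0
) -> MetricsReport:
    """AUROC / accuracy / sensitivity / specificity with 95% bootstrap CIs."""
    negative, positive = result.classes
    y = result.y_true
    y_bin = (y == positive).astype(int)
    point_auroc = auroc(result.scores, y_bin)
    acc_fn, sens_fn, spec_fn = _binary_metric_fns(positive, negative)

    def auroc_fn(labels, scores):
        return auroc(scores, labels == positive)

    metrics = {}
    for name, fn, values in (
        ("auroc", auroc_fn, result.scores),
        ("accuracy", acc_fn, result.predictions),
        ("sensitivity", sens_fn, result.predictions),
        ("specificity", spec_fn, result.predictions),
    ):
        lo, hi = stratified_bootstrap_ci(fn, y, values, n_boot=n_boot, seed=seed)
        metrics[name] = (float(fn(y, values)) if name != "auroc" else point_auroc, lo, hi)
    note = ""
    if result.feature_set == "selected":
        note = (
            "k chosen on the outer test curve; metrics after feature selection "
            "are optimistically biased"
        )
    return MetricsReport(
        task=result.task, model=result.model, metrics=metrics, classes=result.classes, note=note
    )


def _micro_metrics(classes: list[str]):
    idx = {c: i for i, c in enumerate(classes)}
    k = len(classes)

    def micro_auroc(labels, scores):
        onehot = np.zeros((len(labels), k))
        onehot[np.arange(len(labels)), [idx[c] for c in labels]] = 1.0
        return auroc(np.asarray(scores).ravel(), onehot.ravel())

    def micro_sens(labels, preds):
        # pooled one-vs-all TP / (TP + FN) == overall accuracy
        return float(np.mean(preds == labels))

    def micro_spec(labels, preds):
        correct = np.sum(preds == labels)
        n = len(labels)
        # pooled TN = (k-1)*n - (k-1)*errors... each subject contributes
        # (k-1) negatives; an error produces one FP among them.
        errors = n - correct
        return float(((k - 1) * n - errors) / ((k - 1) * n))

    return micro_auroc, micro_sens, micro_spec


def score_multiclass(
    result: NestedCVResult, n_boot: int = 1000, seed: int = 0
) -> MetricsReport:
    """Micro-averaged multiclass metrics and the confusion matrix.

    Micro-AUROC pools the one-vs-all binarized (label, score) pairs over
    all classes; micro-sensitivity is algebraically identical to overall
    accuracy (each subject contributes exactly one positive), which is the
    reason random guessing on a balanced 4-class cohort scores 0.25.
    """
    classes = result.classes
    y = result.y_true
    micro_auroc, micro_sens, micro_spec = _micro_metrics(classes)
    scores = np.asarray(result.scores)
    if scores.ndim != 2 or scores.shape[1] != len(classes):
        raise ValueError("multiclass scoring needs per-class score columns")
    missing = set(classes) - set(np.unique(result.predictions))
    if missing:
        warnings.warn(f"classes never predicted: {sorted(missing)}", stacklevel=2)
    metrics = {}
    point = {
        "auroc": micro_auroc(y, scores),
        "accuracy": float(np.mean(result.predictions == y)),
        "sensitivity": micro_sens(y, result.predictions),
        "specificity": micro_spec(y, result.predictions),
    }
    for name, fn, values in (
        ("auroc", micro_auroc, scores),
        ("accuracy", lambda l, p: float(np.mean(p == l)), result.predictions),
        ("sensitivity", micro_sens, result.predictions),
        ("specificity", micro_spec, result.predictions),
    ):
        lo, hi = stratified_bootstrap_ci(fn, y, values, n_boot=n_boot, seed=seed)
        metrics[name] = (point[name], lo, hi)
    cm = _sk_confusion(y, result.predictions, labels=classes)
    return MetricsReport(
        task=result.task,
        model=result.model,
        metrics=metrics,
        confusion_matrix=cm,
        classes=classes,
    )
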