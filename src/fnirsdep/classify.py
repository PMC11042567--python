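"""Classifier training and evaluation: stratified 60/40 split, grid-search
hyperparameter tuning, nested cross-validation, and the standard binary
metrics (AUC, accuracy, sensitivity, specificity, F1).

Four model families are benchmarked on temporal (TF), correlation (CF) and
fused (TCF) feature sets: random forest, logistic regression, multi-layer
perceptron and support vector machine.  Features are z-scored with
statistics fitted on training folds only (inside a sklearn Pipeline), so
no test subject ever influences scaling, tuning or selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import FeatureTable

__all__ = [
    "SplitSpec",
    "EvalReport",
    "MODEL_NAMES",
    "default_grid",
    "make_model",
    "stratified_split",
    "grid_search_fit",
    "nested_cv_evaluate",
    "classification_metrics",
    "run_model_comparison",
]

MODEL_NAMES = ("RF", "LR", "MLP", "SVM")
POSITIVE_CLASS = "severe"


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split specification."""

    train_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train fraction must be in (0, 1)")


def make_model(name: str, seed: int = 0):
    """Instantiate one of the four benchmark classifiers."""
    if name == "RF":
        return RandomForestClassifier(random_state=seed)
    if name == "LR":
        return LogisticRegression(max_iter=5000, random_state=seed)
    if name == "MLP":
        return MLPClassifier(max_iter=800, random_state=seed)
    if name == "SVM":
        return SVC(random_state=seed)
    raise ValueError(f"unknown model: {name!r}")


def default_grid(name: str) -> list[dict] | dict:
    """Hyperparameter lattice searched for each model family."""
    c_range = [0.01, 0.1, 1.0, 10.0, 100.0]
    if name == "SVM":
        return [
            {"clf__kernel": ["linear"], "clf__C": c_range},
            {"clf__kernel": ["rbf"], "clf__C": c_range,
             "clf__gamma": ["scale", 0.001, 0.01, 0.1, 1.0]},
        ]
    if name == "LR":
        return {"clf__C": c_range}
    if name == "RF":
        return {"clf__n_estimators": [100, 300],
                "clf__max_depth": [3, 5, None]}
    if name == "MLP":
        return {"clf__hidden_layer_sizes": [(16,), (64,)],
                "clf__alpha": [1e-4, 1e-2]}
    raise ValueError(f"unknown model: {name!r}")


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


def stratified_split(labels: dict[str, str] | "pd.Series",
                     spec: SplitSpec | None = None
                     ) -> tuple[list[str], list[str]]:
    """Per-class deterministic split: round-half-up of fraction × class
    size to train, remainder to test.

    With 82 severe + 58 mild at fraction 0.6 this yields train (49, 35) and
    test (33, 23).
    """
    spec = spec or SplitSpec()
    items = list(labels.items())
    classes: dict[str, list[str]] = {}
    for sid, lab in items:
        classes.setdefault(lab, []).append(sid)
    rng = np.random.default_rng(spec.seed)
    train, test = [], []
    for lab in sorted(classes):
        ids = sorted(classes[lab])
        if len(ids) < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 subjects")
        n_train = _round_half_up(spec.train_fraction * len(ids))
        if n_train == 0 or n_train == len(ids):
            raise ValueError(
                f"fraction {spec.train_fraction} leaves class {lab!r} "
                "with an empty partition"
            )
        perm = rng.permutation(len(ids))
        train += [ids[i] for i in perm[:n_train]]
        test += [ids[i] for i in perm[n_train:]]
    return sorted(train), sorted(test)


def _pipeline(model_name: str, seed: int) -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("clf", make_model(model_name, seed)),
    ])


def grid_search_fit(train: FeatureTable, model_name: str,
                    grid: dict | list | None = None, inner_folds: int = 5,
                    seed: int = 0) -> GridSearchCV:
    """Exhaustive grid search by stratified inner-CV accuracy.

    Rows are canonicalized by subject id before fitting, so the chosen
    parameters do not depend on the order subjects were supplied in.  Ties
    resolve to the first configuration in lattice order.
    """
    train = train.sorted_by_id()
    grid = grid if grid is not None else default_grid(model_name)
    if not grid:
        raise ValueError("empty parameter grid")
    cv = StratifiedKFold(inner_folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(_pipeline(model_name, seed), grid, cv=cv,
                      scoring="accuracy", refit=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gs.fit(train.X(), train.y())
    return gs


def _decision_scores(fitted, X: np.ndarray,
                     classes: np.ndarray) -> np.ndarray:
    """Continuous scores for the positive class."""
    if hasattr(fitted, "decision_function"):
        s = fitted.decision_function(X)
        # decision_function is oriented toward classes[1]
        return s if classes[1] == POSITIVE_CLASS else -s
    proba = fitted.predict_proba(X)
    pos_col = int(np.flatnonzero(classes == POSITIVE_CLASS)[0])
    return proba[:, pos_col]


def classification_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                           scores: np.ndarray | None = None,
                           positive: str = POSITIVE_CLASS) -> dict:
    """Confusion-matrix metrics plus trapezoidal ROC AUC.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/total, F1 = 2·precision·sensitivity /
    (precision+sensitivity).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must share length")
    pos = y_true == positive
    pred_pos = y_pred == positive
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    total = tp + fn + tn + fp
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / total
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * prec * sens / (prec + sens)) if prec + sens > 0 else 0.0
    out = {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "f1": f1,
    }
    if scores is not None:
        if len(np.unique(y_true)) < 2:
            raise ValueError("AUC undefined for single-class labels")
        out["auc"] = float(roc_auc_score(pos.astype(int), scores))
    return out


def nested_cv_evaluate(table: FeatureTable, model_name: str,
                       grid: dict | list | None = None, outer_folds: int = 5,
                       inner_folds: int = 5, seed: int = 0) -> dict:
    """Nested cross-validation: grid search in the inner loop, metrics on
    the outer held-out folds only; no subject appears on both sides of any
    fold.
    """
    table = table.sorted_by_id()
    X, y = table.X(), table.y()
    classes = np.unique(y)
    if min(np.bincount(np.searchsorted(classes, y))) < outer_folds:
        raise ValueError("too few subjects per class for the outer folds")
    outer = StratifiedKFold(outer_folds, shuffle=True, random_state=seed)
    fold_metrics = []
    chosen = []
    for tr_idx, te_idx in outer.split(X, y):
        assert not set(tr_idx) & set(te_idx)
        sub = FeatureTable(table.values.iloc[tr_idx],
                           table.labels.iloc[tr_idx])
        gs = grid_search_fit(sub, model_name, grid, inner_folds, seed)
        y_pred = gs.predict(X[te_idx])
        scores = _decision_scores(gs, X[te_idx], gs.classes_)
        fold_metrics.append(
            classification_metrics(y[te_idx], y_pred, scores)
        )
        chosen.append({k.replace("clf__", ""): v
                       for k, v in gs.best_params_.items()})
    agg = {
        m: {
            "mean": float(np.mean([f[m] for f in fold_metrics])),
            "sd": float(np.std([f[m] for f in fold_metrics])),
        }
        for m in fold_metrics[0]
    }
    return {"folds": fold_metrics, "aggregate": agg,
            "chosen_params": chosen}


@dataclass
class EvalReport:
    """Per-model, per-feature-set metrics from the held-out test split and
    (optionally) nested CV."""

    results: dict = field(default_factory=dict)

    def set_cell(self, model: str, feature_set: str, payload: dict) -> None:
        self.results.setdefault(model, {})[feature_set] = payload
        self._check(payload.get("test", {}))

    @staticmethod
    def _check(metrics: dict) -> None:
        for k, v in metrics.items():
            if isinstance(v, float) and np.isfinite(v) and not 0 <= v <= 1:
                raise ValueError(f"metric {k} out of [0,1]: {v}")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.results, fh, indent=2)
        return path


def run_model_comparison(tables: dict[str, FeatureTable],
                         split: SplitSpec | None = None,
                         models: tuple[str, ...] = MODEL_NAMES,
                         grids: dict | None = None, seed: int = 0,
                         include_nested: bool = False,
                         inner_folds: int = 5) -> EvalReport:
    """Evaluate each model on each feature set (TF, CF, TCF).

    Per cell: stratified 60/40 split, grid search on the training split,
    metrics on the held-out test split; optional nested CV on the full
    table.  The same split (same seed) is used for every cell.
    """
    split = split or SplitSpec(seed=seed)
    report = EvalReport()
    first = next(iter(tables.values()))
    train_ids, test_ids = stratified_split(first.labels.to_dict(), split)
    for model in models:
        for fs_name, table in tables.items():
            grid = (grids or {}).get(model) if grids else None
            tr = table.subset_subjects(train_ids)
            te = table.subset_subjects(test_ids)
            gs = grid_search_fit(tr, model, grid, inner_folds, seed)
            y_pred = gs.predict(te.X())
            scores = _decision_scores(gs, te.X(), gs.classes_)
            cell = {
                "test": classification_metrics(te.y(), y_pred, scores),
                "best_params": {k.replace("clf__", ""): v
                                for k, v in gs.best_params_.items()},
            }
            if include_nested:
                cell["nested_cv"] = nested_cv_evaluate(
                    table, model, grid, 5, inner_folds, seed
                )["aggregate"]
            report.set_cell(model, fs_name, cell)
    return report
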