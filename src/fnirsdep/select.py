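"""Two-pass recursive feature elimination with cross-validation (RFECV).

Pass 1 screens the temporal-feature (TF) and correlation-feature (CF)
tables independently; the survivors are fused and pass 2 selects the final
subset.  The base estimator is a linear maximum-margin classifier whose
coefficient magnitudes serve as feature importances; the subset size is the
one maximizing mean cross-validated accuracy (ties break toward the
smaller subset).  Selection must only ever see training subjects — the
leakage contract is the caller's responsibility and is exercised by the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.feature_selection import RFECV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import FeatureTable

__all__ = ["SelectionResult", "rfecv_select", "two_pass_select"]


@dataclass
class SelectionResult:
    """Outcome of one RFECV pass."""

    selected_mask: np.ndarray      # per-feature boolean
    ranking: np.ndarray            # 1 = retained longest
    cv_curve: np.ndarray           # mean CV accuracy per evaluated size
    n_features_grid: np.ndarray    # subset sizes matching cv_curve
    n_selected: int
    feature_names: list[str]

    def selected_names(self) -> list[str]:
        return [n for n, keep in zip(self.feature_names, self.selected_mask)
                if keep]

    def to_dict(self) -> dict:
        return {
            "n_selected": int(self.n_selected),
            "selected": self.selected_names(),
            "ranking": self.ranking.astype(int).tolist(),
            "cv_curve": self.cv_curve.tolist(),
            "n_features_grid": self.n_features_grid.astype(int).tolist(),
        }


def _default_estimator(seed: int) -> SVC:
    return SVC(kernel="linear", C=1.0, random_state=seed)


def rfecv_select(table: FeatureTable, estimator=None, cv_folds: int = 5,
                 step: int = 1, seed: int = 0,
                 min_features: int = 1) -> SelectionResult:
    """One RFECV pass over a feature table.

    Features are z-scored over the given table (which, per the leakage
    contract, holds training subjects only) before elimination.
    """
    y = table.y()
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes for selection")
    if table.n_features < 1:
        raise ValueError("need at least one feature")
    est = estimator if estimator is not None else _default_estimator(seed)
    X = StandardScaler().fit_transform(table.X())
    if table.n_features == 1:
        return SelectionResult(
            selected_mask=np.array([True]),
            ranking=np.array([1]),
            cv_curve=np.array([np.nan]),
            n_features_grid=np.array([1]),
            n_selected=1,
            feature_names=table.feature_names,
        )
    cv = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
    rfecv = RFECV(est, step=step, cv=cv, scoring="accuracy",
                  min_features_to_select=min_features)
    rfecv.fit(X, y)
    curve = np.asarray(rfecv.cv_results_["mean_test_score"])
    grid = np.asarray(rfecv.cv_results_.get(
        "n_features",
        np.arange(min_features, min_features + curve.size),
    ))
    return SelectionResult(
        selected_mask=rfecv.support_.copy(),
        ranking=rfecv.ranking_.copy(),
        cv_curve=curve,
        n_features_grid=grid,
        n_selected=int(rfecv.n_features_),
        feature_names=table.feature_names,
    )


def two_pass_select(tf_table: FeatureTable, cf_table: FeatureTable,
                    estimator=None, cv_folds: int = 5, step: int = 1,
                    seed: int = 0
                    ) -> tuple[FeatureTable, dict[str, SelectionResult]]:
    """Screen TF and CF independently, fuse survivors, re-select.

    Returns the final fused-and-reduced FeatureTable plus the three
    SelectionResults (keys ``tf``, ``cf``, ``fused``).
    """
    if list(tf_table.values.index) != list(cf_table.values.index):
        raise ValueError("TF and CF tables must cover the same subjects")
    if not np.array_equal(tf_table.y(), cf_table.y()):
        raise ValueError("TF and CF tables must share the label vector")

    res_tf = rfecv_select(tf_table, estimator, cv_folds, step, seed)
    res_cf = rfecv_select(cf_table, estimator, cv_folds, step, seed)
    tf_keep = res_tf.selected_names()
    cf_keep = res_cf.selected_names()
    if not tf_keep and not cf_keep:
        raise ValueError("first pass eliminated every feature; "
                         "check labels and signal strength")

    fused_values = tf_table.values[tf_keep].join(cf_table.values[cf_keep])
    fused = FeatureTable(fused_values, tf_table.labels.copy())
    res_fused = rfecv_select(fused, estimator, cv_folds, step, seed)
    final = fused.subset_features(res_fused.selected_names())
    return final, {"tf": res_tf, "cf": res_cf, "fused": res_fused}
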