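"""Grid-searched tree-ensemble classifiers, metrics, and feature screening.

Four algorithm families are supported -- gradient boosting (gbm), random
forest (rf), LightGBM (lgbm), and XGBoost (xgb) -- each tuned by k-fold
(default tenfold) cross-validated grid search on ROC AUC and then refit on
the full training set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .errors import TrainError

# lightgbm's sklearn wrapper invents column names for array input, which
# trips sklearn's name-consistency check on every predict call
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names"
)

ALGORITHMS = ("gbm", "rf", "lgbm", "xgb")

# Full-scale default grids (editable config).  Only the hyperparameters
# tuned per family are gridded: gbm {n_estimators, max_depth, max_features,
# learning_rate}; lgbm {n_estimators, learning_rate}; rf {n_estimators,
# max_features}; xgb {n_estimators, max_depth, learning_rate}.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "gbm": {
        "n_estimators": [500, 1000, 3000],
        "max_depth": [10, 15],
        "max_features": ["sqrt", "log2", None],
        "learning_rate": [0.01, 0.05],
    },
    "lgbm": {
        "n_estimators": [500, 1000, 3000],
        "learning_rate": [0.01, 0.05],
    },
    "rf": {
        "n_estimators": [500, 1000, 3000],
        "max_features": ["sqrt", "log2", None],
    },
    "xgb": {
        "n_estimators": [500, 1000, 3000],
        "max_depth": [10, 15],
        "learning_rate": [0.01, 0.05],
    },
}

# Desk-scale grids for quick runs on small synthetic sets.
COMPACT_GRIDS: dict[str, dict[str, list]] = {
    "gbm": {"n_estimators": [200], "max_depth": [3], "learning_rate": [0.1]},
    "lgbm": {"n_estimators": [200, 400], "learning_rate": [0.1]},
    "rf": {"n_estimators": [300], "max_features": ["sqrt", "log2"]},
    "xgb": {"n_estimators": [200, 400], "max_depth": [4], "learning_rate": [0.1]},
}


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str
    grid: Mapping[str, list] | None = None
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.grid is not None and not self.grid:
            raise ValueError("grid must be non-empty")

    def resolved_grid(self) -> dict[str, list]:
        return dict(self.grid) if self.grid is not None else DEFAULT_GRIDS[self.algorithm]


def _base_estimator(algorithm: str, seed: int):
    if algorithm == "gbm":
        return GradientBoostingClassifier(random_state=seed)
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if algorithm == "lgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            random_state=seed, n_jobs=1, verbose=-1, deterministic=True,
            force_row_wise=True, importance_type="gain",
        )
    if algorithm == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed, n_jobs=1, verbosity=0, eval_metric="logloss",
        )
    raise ValueError(algorithm)


@dataclass
class TrainedModel:
    """A grid-search winner refit on the whole training set."""

    estimator: object
    algorithm: str
    best_params: dict
    cv_auc_mean: float
    cv_auc_sd: float
    train_auc: float
    descriptor_set: str = "F46"
    feature_names: list[str] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(np.asarray(X))[:, 1]


def train_with_gridsearch(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    descriptor_set: str = "F46",
    feature_names: list[str] | None = None,
) -> TrainedModel:
    """Tune by mean CV AUC over a stratified k-fold grid search, then refit
    the winning hyperparameters on all training rows."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise TrainError("training labels contain a single class")
    if len(y) < 2 * spec.cv_folds:
        raise TrainError(
            f"need >= {2 * spec.cv_folds} records for {spec.cv_folds}-fold CV"
        )
    cv = StratifiedKFold(
        n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed
    )
    search = GridSearchCV(
        _base_estimator(spec.algorithm, spec.seed),
        param_grid=spec.resolved_grid(),
        scoring="roc_auc",
        cv=cv,
        refit=True,
        n_jobs=1,
    )
    search.fit(X, y)
    best_idx = search.best_index_
    return TrainedModel(
        estimator=search.best_estimator_,
        algorithm=spec.algorithm,
        best_params=dict(search.best_params_),
        cv_auc_mean=float(search.cv_results_["mean_test_score"][best_idx]),
        cv_auc_sd=float(search.cv_results_["std_test_score"][best_idx]),
        train_auc=float(
            roc_auc_score(y, search.best_estimator_.predict_proba(X)[:, 1])
        ),
        descriptor_set=descriptor_set,
        feature_names=list(feature_names or []),
    )


@dataclass(frozen=True)
class EvalMetrics:
    auc: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    threshold: float = 0.5

    def to_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc, "accuracy": self.accuracy,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "threshold": self.threshold,
        }


def metrics_from_scores(
    y: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> EvalMetrics:
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(y).size < 2:
        raise TrainError("AUC undefined for single-class labels")
    pred = (scores >= threshold).astype(int)
    return EvalMetrics(
        auc=float(roc_auc_score(y, scores)),
        accuracy=float(accuracy_score(y, pred)),
        precision=float(precision_score(y, pred, zero_division=0)),
        recall=float(recall_score(y, pred, zero_division=0)),
        f1=float(f1_score(y, pred, zero_division=0)),
        threshold=threshold,
    )


def evaluate(
    model: TrainedModel, X: np.ndarray, y: np.ndarray, threshold: float = 0.5
) -> EvalMetrics:
    """Threshold-free AUC plus accuracy/precision/recall/F1 at ``threshold``."""
    return metrics_from_scores(y, model.predict_proba(X), threshold)


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def feature_screen(
    features: pd.DataFrame,
    labels: np.ndarray,
    welch: bool = False,
    orient_auc: bool = False,
) -> pd.DataFrame:
    """Per-feature single-variable screening.

    For each column: ROC AUC using the raw feature value as the score
    (reported unoriented by default, so inversely predictive features fall
    below 0.5), a two-sample two-tailed Student's t-test between classes
    (Welch variant by flag), and significance stars at 0.05/0.01/0.001.
    """
    y = np.asarray(labels, dtype=int)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise TrainError("need >= 2 records per class for screening")
    rows = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        ok = np.isfinite(x)
        xv, yv = x[ok], y[ok]
        pos, neg = xv[yv == 1], xv[yv == 0]
        if xv.std() == 0 or len(pos) < 2 or len(neg) < 2:
            rows.append(
                {"feature": name, "auc": np.nan, "t": np.nan,
                 "p": np.nan, "stars": "", "zero_variance": True}
            )
            continue
        auc = roc_auc_score(yv, xv)
        if orient_auc:
            auc = max(auc, 1.0 - auc)
        t, p = stats.ttest_ind(pos, neg, equal_var=not welch)
        rows.append(
            {"feature": name, "auc": float(auc), "t": float(t),
             "p": float(p), "stars": _stars(float(p)),
             "zero_variance": False}
        )
    return pd.DataFrame(rows).set_index("feature")


def feature_importance(model: TrainedModel) -> pd.Series:
    """Normalised per-feature importances of a tree ensemble (sum to 1)."""
    est = model.estimator
    if not hasattr(est, "feature_importances_"):
        raise TrainError(
            f"{model.algorithm}: estimator does not expose importances"
        )
    imp = np.asarray(est.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    names = (
        model.feature_names
        if len(model.feature_names) == imp.size
        else [f"f{i}" for i in range(imp.size)]
    )
    return pd.Series(imp, index=names).sort_values(ascending=False)
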