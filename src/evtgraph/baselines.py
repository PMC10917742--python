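"""Comparison classifiers behind one train/predict contract.

Four standard tabular algorithms — logistic regression, random forest, a
fully connected network and XGBoost — each tuned by exhaustive grid search
maximizing validation AUC, with the grids used in the study. The evaluation
layer treats these and the graph network interchangeably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import NotFittedError
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

from .preprocess import FeatureMatrix

__all__ = ["ALGORITHMS", "BaselineSpec", "default_grids", "small_grids",
           "fit_baseline", "predict_proba"]

logger = logging.getLogger(__name__)

ALGORITHMS = ("logistic_regression", "random_forest", "fully_connected", "xgboost")

# the fully connected network's architecture is fixed; only optimizer and
# learning rate are searched
FCN_HIDDEN = (128, 64, 32, 16, 8)


@dataclass
class BaselineSpec:
    algorithm: str
    grid: dict
    chosen: dict | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("grid must be non-empty in every dimension")


def default_grids() -> dict[str, dict]:
    """Hyperparameter grids as used in the study."""
    return {
        "logistic_regression": {
            "C": [1000, 100, 10],
            "solver": ["newton-cholesky", "liblinear"],
        },
        "random_forest": {
            "n_estimators": [2, 5, 10, 100],
            "max_features": ["log2", "sqrt", 2, 5, 10, 100],
            "max_depth": [5, 10, None],
            "bootstrap": [True, False],
            "criterion": ["gini", "entropy"],
        },
        "fully_connected": {
            "solver": ["sgd", "adam"],
            "learning_rate_init": [0.1, 0.01, 0.001, 0.0001],
        },
        "xgboost": {
            "max_depth": [2, 4, 6],
            "subsample": [0.6, 0.8, 1.0],
            "colsample_bytree": [0.4, 0.6, 0.8, 1.0],
            "gamma": [0.5, 1, 1.5, 2.5],
        },
    }


def small_grids() -> dict[str, dict]:
    """Reduced grids for quick runs (same dimensions, fewer candidates)."""
    return {
        "logistic_regression": {"C": [100, 10], "solver": ["liblinear"]},
        "random_forest": {
            "n_estimators": [10, 100],
            "max_features": ["sqrt"],
            "max_depth": [5, None],
            "bootstrap": [True],
            "criterion": ["gini"],
        },
        "fully_connected": {"solver": ["adam"], "learning_rate_init": [0.01, 0.001]},
        "xgboost": {
            "max_depth": [2, 4],
            "subsample": [0.8],
            "colsample_bytree": [0.8],
            "gamma": [1],
        },
    }


def _make_model(algorithm: str, params: dict, n_features: int, seed: int):
    params = dict(params)
    if algorithm == "logistic_regression":
        return LogisticRegression(
            penalty="l2", max_iter=5000, tol=1e-6, random_state=seed, **params
        )
    if algorithm == "random_forest":
        mf = params.get("max_features")
        if isinstance(mf, (int, np.integer)) and mf > n_features:
            return None  # invalid for this design matrix; filtered by caller
        return RandomForestClassifier(random_state=seed, **params)
    if algorithm == "fully_connected":
        return MLPClassifier(
            hidden_layer_sizes=FCN_HIDDEN,
            activation="relu",
            max_iter=400,
            random_state=seed,
            **params,
        )
    if algorithm == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=200,
            learning_rate=0.1,
            eval_metric="logloss",
            early_stopping_rounds=20,
            random_state=seed,
            verbosity=0,
            **params,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def fit_baseline(
    spec: BaselineSpec,
    matrix: FeatureMatrix,
    train_mask: np.ndarray,
    val_mask: np.ndarray,
    seed: int = 0,
):
    """Exhaustive grid search on the validation split.

    Returns ``(model, chosen_params, grid_table)`` where the winner maximizes
    validation AUC (ties resolve to the first configuration in deterministic
    grid order). Test rows are never touched.
    """
    train_mask = np.asarray(train_mask, bool)
    val_mask = np.asarray(val_mask, bool)
    Xtr, ytr = matrix.X[train_mask], matrix.y[train_mask]
    Xva, yva = matrix.X[val_mask], matrix.y[val_mask]
    if np.unique(ytr).size < 2:
        raise ValueError("training mask holds a single class")
    if np.unique(yva).size < 2:
        raise ValueError("validation mask holds a single class")

    best_model, best_params, best_auc = None, None, -np.inf
    grid_table = []
    for params in ParameterGrid(spec.grid):
        model = _make_model(spec.algorithm, params, Xtr.shape[1], seed)
        if model is None:
            logger.info("skipping invalid configuration %s", params)
            continue
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence noise etc.
            if spec.algorithm == "xgboost":
                model.fit(Xtr, ytr, eval_set=[(Xva, yva)], verbose=False)
            else:
                model.fit(Xtr, ytr)
        auc = float(roc_auc_score(yva, model.predict_proba(Xva)[:, 1]))
        grid_table.append({**params, "val_auc": auc})
        if auc > best_auc:
            best_model, best_params, best_auc = model, dict(params), auc
    if best_model is None:
        raise ValueError("no valid configuration in the grid")
    spec.chosen = best_params
    return best_model, best_params, grid_table


def predict_proba(model, matrix: FeatureMatrix, rows: np.ndarray | None = None):
    """Positive-class probabilities for the given rows (all rows if None)."""
    try:
        check_is_fitted(model)
    except NotFittedError as exc:
        raise ValueError("model is not fitted") from exc
    X = matrix.X if rows is None else matrix.X[np.asarray(rows)]
    return model.predict_proba(X)[:, 1]
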