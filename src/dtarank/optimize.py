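"""Feature-set optimization: variance thresholding, PCA projection, Lasso
selection with cross-validated alpha, and boosted-tree importance
selection (select-from-model semantics) over the XGBoost and LightGBM
backends.

Every selector fits on training rows only.  Linear methods (PCA, Lasso)
standardize columns with training statistics first; tree backends consume
raw features.  Default hyperparameter search spaces follow the
grid-search ranges conventional for this pipeline (see ``DEFAULT_GRIDS``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from .features import FeatureTable

__all__ = [
    "SelectionResult",
    "DEFAULT_GRIDS",
    "variance_filter",
    "pca_project",
    "lasso_select",
    "tree_select",
    "grid_search",
]

Method = Literal["VT", "PCA", "Lasso", "XGB", "Light", "Cat"]

#: Grid-search spaces per boosted-tree backend; VT sweeps
#: numpy.linspace(0.01, 0.1, 5), Lasso's alpha is chosen by 5-fold CV.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "xgb": {
        "n_estimators": [200, 400, 600, 800],
        "max_depth": [3, 4, 5, 6],
        "learning_rate": [0.02, 0.04, 0.06, 0.08],
    },
    "light": {
        "n_estimators": [200, 400, 600, 800],
        "max_depth": [3, 4, 5, 6],
        "learning_rate": [0.02, 0.04, 0.06, 0.08],
    },
    "vt_thresholds": {"threshold": list(np.linspace(0.01, 0.1, 5))},
    "lasso_alphas": {"alpha": list(np.logspace(-4, 0, 9))},
}


@dataclass
class SelectionResult:
    """Outcome of one feature-optimization method."""

    method: Method
    selected: list[str]  # ordered feature names (components for PCA)
    scores: dict[str, float]  # per-feature importance / |coefficient| / variance
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def num(self) -> int:
        """Retained dimension, the "num" column of comparison tables."""
        return len(self.selected)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "method": self.method,
                    "selected": self.selected,
                    "scores": self.scores,
                    "hyperparameters": self.hyperparameters,
                    "seed": self.seed,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return cls(
            method=d["method"],
            selected=d["selected"],
            scores=d["scores"],
            hyperparameters=d["hyperparameters"],
            seed=d["seed"],
        )


def variance_filter(table: FeatureTable, threshold: float = 0.0) -> SelectionResult:
    """Drop every column whose variance over the training rows is <= the
    threshold; retain the rest in their original order."""
    if threshold < 0:
        raise ValueError("variance threshold must be >= 0")
    variances = table.X.to_numpy().var(axis=0)  # population variance (ddof=0)
    keep = variances > threshold
    if not keep.any():
        raise ValueError(
            f"variance threshold {threshold} removes every column; "
            "lower the threshold"
        )
    names = table.feature_names
    return SelectionResult(
        method="VT",
        selected=[n for n, k in zip(names, keep) if k],
        scores={n: float(v) for n, v in zip(names, variances)},
        hyperparameters={"threshold": threshold},
    )


def pca_project(
    train: FeatureTable,
    test: FeatureTable | None = None,
    component_policy: int | Literal["mle"] = "mle",
) -> tuple[FeatureTable, FeatureTable | None, SelectionResult]:
    """Standardize on training statistics, fit PCA on training rows only,
    and project train (and test).  ``component_policy='mle'`` selects the
    dimension by the maximum-likelihood criterion; an integer fixes it."""
    X = train.X.to_numpy()
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 training rows")
    if isinstance(component_policy, int) and not (
        1 <= component_policy <= min(X.shape)
    ):
        raise ValueError(
            f"n_components {component_policy} must be in [1, {min(X.shape)}]"
        )
    scaler = StandardScaler().fit(X)
    pca = PCA(n_components=component_policy, svd_solver="full")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        z_train = pca.fit_transform(scaler.transform(X))

    comp_names = [f"PC{i + 1}" for i in range(pca.n_components_)]

    def project(tbl: FeatureTable, z: np.ndarray | None = None) -> FeatureTable:
        if z is None:
            z = pca.transform(scaler.transform(tbl.X.to_numpy()))
        return FeatureTable(
            list(tbl.pairs),
            pd.DataFrame(z, columns=comp_names),
            tbl.y.copy(),
            tbl.query.copy(),
            {c: {"block": "PCA", "statistic": c} for c in comp_names},
        )

    result = SelectionResult(
        method="PCA",
        selected=comp_names,
        scores={
            c: float(v) for c, v in zip(comp_names, pca.explained_variance_ratio_)
        },
        hyperparameters={
            "component_policy": component_policy,
            "n_components": int(pca.n_components_),
            "svd_solver": "full",
        },
    )
    return project(train, z_train), (project(test) if test is not None else None), result


def lasso_select(
    table: FeatureTable,
    alpha_grid: Sequence[float] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """L1-regularized linear selection: alpha chosen by k-fold
    cross-validated MSE on standardized training rows; selected features
    are those with a non-zero coefficient at the winning alpha."""
    alphas = list(alpha_grid) if alpha_grid is not None else list(
        DEFAULT_GRIDS["lasso_alphas"]["alpha"]
    )
    if not alphas or any(a <= 0 for a in alphas):
        raise ValueError("alpha grid must be non-empty with all alphas > 0")
    X = StandardScaler().fit_transform(table.X.to_numpy())
    y = table.y
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_mse = []
    for alpha in alphas:
        errs = []
        for tr, va in kf.split(X):
            model = Lasso(alpha=alpha, max_iter=5000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[tr], y[tr])
            errs.append(np.mean((y[va] - model.predict(X[va])) ** 2))
        cv_mse.append(float(np.mean(errs)))
    best_alpha = alphas[int(np.argmin(cv_mse))]
    final = Lasso(alpha=best_alpha, max_iter=10000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)
    coefs = np.abs(final.coef_)
    names = table.feature_names
    selected = [n for n, c in zip(names, coefs) if c > 0]
    if not selected:
        warnings.warn(
            "Lasso selected zero features at every alpha; returning an empty "
            "selection",
            stacklevel=2,
        )
    return SelectionResult(
        method="Lasso",
        selected=selected,
        scores={n: float(c) for n, c in zip(names, coefs)},
        hyperparameters={
            "alpha": float(best_alpha),
            "alpha_grid": [float(a) for a in alphas],
            "folds": folds,
            "cv_mse": cv_mse,
        },
        seed=seed,
    )


def _fit_backend(backend: str, params: Mapping, X, y, seed: int):
    """Fit one boosted-tree regressor; returns (model, gain_importances)."""
    if backend == "xgb":
        import xgboost as xgb

        model = xgb.XGBRegressor(
            n_estimators=int(params.get("n_estimators", 400)),
            max_depth=int(params.get("max_depth", 4)),
            learning_rate=float(params.get("learning_rate", 0.06)),
            objective="reg:squarederror",
            importance_type="total_gain",
            n_jobs=1,
            random_state=seed,
            verbosity=0,
        )
        model.fit(X, y)
        return model, np.asarray(model.feature_importances_, dtype=float)
    if backend == "light":
        import lightgbm as lgb

        max_depth = int(params.get("max_depth", 4))
        model = lgb.LGBMRegressor(
            boosting_type="gbdt",
            n_estimators=int(params.get("n_estimators", 400)),
            max_depth=max_depth,
            num_leaves=2**max_depth - 1,
            learning_rate=float(params.get("learning_rate", 0.06)),
            n_jobs=1,
            random_state=seed,
            deterministic=True,
            force_row_wise=True,
            verbosity=-1,
        )
        model.fit(X, y)
        gain = model.booster_.feature_importance(importance_type="gain")
        return model, np.asarray(gain, dtype=float)
    if backend == "cat":
        raise RuntimeError(
            "the 'cat' backend requires the catboost package, which is not "
            "installed in this environment; use backend 'xgb' or 'light'"
        )
    raise ValueError(f"unknown backend {backend!r}")


def grid_search(
    table: FeatureTable,
    backend: Literal["xgb", "light"],
    grid: Mapping[str, Sequence] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[dict, float]:
    """Exhaustive grid search by k-fold cross-validated MSE on the training
    rows; returns (best_params, best_cv_mse)."""
    grid = dict(grid) if grid is not None else dict(DEFAULT_GRIDS[backend])
    keys = list(grid)
    X, y = table.X.to_numpy(), table.y
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    best_params, best_mse = None, np.inf
    for combo in product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        errs = []
        for tr, va in splits:
            model, _ = _fit_backend(backend, params, X[tr], y[tr], seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                pred = model.predict(X[va])
            errs.append(np.mean((y[va] - pred) ** 2))
        cv = float(np.mean(errs))
        if cv < best_mse:
            best_params, best_mse = params, cv
    return best_params, best_mse


def tree_select(
    table: FeatureTable,
    backend: Literal["xgb", "light", "cat"] = "light",
    grid: Mapping[str, Sequence] | None = None,
    importance_rule: Literal["mean", "median"] = "mean",
    folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Select-from-model on a grid-searched boosted-tree regressor.

    The backend is fitted at the best grid point (5-fold CV MSE), features
    are scored by total gain, and those with importance >= the
    ``importance_rule`` statistic of the *non-zero* importances are kept,
    in original column order.
    """
    if backend == "cat":
        _fit_backend("cat", {}, None, None, seed)  # raises the explicit error
    best_params, best_mse = grid_search(table, backend, grid, folds, seed)
    model, importances = _fit_backend(
        backend, best_params, table.X.to_numpy(), table.y, seed
    )
    nonzero = importances[importances > 0]
    if nonzero.size == 0:
        warnings.warn(
            "no feature received non-zero importance; selection is empty",
            stacklevel=2,
        )
        cutoff = np.inf
    else:
        cutoff = float(np.mean(nonzero) if importance_rule == "mean"
                       else np.median(nonzero))
    names = table.feature_names
    selected = [n for n, imp in zip(names, importances) if imp >= cutoff]
    method = {"xgb": "XGB", "light": "Light", "cat": "Cat"}[backend]
    return SelectionResult(
        method=method,
        selected=selected,
        scores={n: float(v) for n, v in zip(names, importances)},
        hyperparameters={
            **(best_params or {}),
            "importance_rule": importance_rule,
            "importance_cutoff": None if np.isinf(cutoff) else cutoff,
            "cv_mse": best_mse,
            "folds": folds,
        },
        seed=seed,
    )
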