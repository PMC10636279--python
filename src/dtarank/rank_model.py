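"""MART-style learning-to-rank regressor over the pair feature table.

Multiple additive regression trees (MART) are realized as squared-error
gradient boosting: the model is trained as a regressor, which both fits
the affinity values and induces a ranking within each query — the
regression-flavored reading of learning-to-rank that fits one-to-many
drug/target association.  A pairwise ranking objective (LambdaMART-style)
is available as an optional mode but is not the default.

Backends: LightGBM (default; double-precision predictions and SHAP) and
XGBoost.  Fits are single-threaded and seeded so that identical inputs
produce bit-identical serialized models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .features import FeatureTable

__all__ = ["RankModel", "DEFAULT_PARAMS", "train", "predict"]

Backend = Literal["lgbm", "xgb"]

#: Mid-grid defaults from the boosted-tree search space
#: (n_estimators {200..800}, max_depth {3..6}, learning_rate {0.02..0.08}).
DEFAULT_PARAMS: dict = {
    "n_estimators": 400,
    "max_depth": 4,
    "learning_rate": 0.06,
}


def _lgbm_params(params: Mapping, seed: int, objective: str) -> dict:
    max_depth = int(params.get("max_depth", 4))
    out = {
        "objective": "regression" if objective == "regression" else "lambdarank",
        "learning_rate": float(params.get("learning_rate", 0.06)),
        "max_depth": max_depth,
        "num_leaves": int(params.get("num_leaves", 2**max_depth - 1)),
        "min_data_in_leaf": int(params.get("min_data_in_leaf", 20)),
        "num_threads": 1,
        "deterministic": True,
        "force_row_wise": True,
        "seed": int(seed),
        "verbosity": -1,
    }
    return out


def _xgb_params(params: Mapping, seed: int, objective: str) -> dict:
    return {
        "objective": (
            "reg:squarederror" if objective == "regression" else "rank:pairwise"
        ),
        "learning_rate": float(params.get("learning_rate", 0.06)),
        "max_depth": int(params.get("max_depth", 4)),
        "nthread": 1,
        "seed": int(seed),
        "verbosity": 0,
    }


@dataclass
class RankModel:
    """A fitted boosted-tree ranker plus the metadata needed to reuse it."""

    backend: Backend
    params: dict
    feature_names: list[str]
    seed: int
    objective: str = "regression"
    booster: object = field(default=None, repr=False)

    # ---- prediction --------------------------------------------------

    def _check_columns(self, X: pd.DataFrame) -> None:
        if list(X.columns) == self.feature_names:
            return
        missing = [c for c in self.feature_names if c not in X.columns]
        extra = [c for c in X.columns if c not in self.feature_names]
        raise ValueError(
            "feature columns do not match the fitted model: "
            f"missing={missing[:5]}, extra={extra[:5]}, "
            "order must match fit time"
        )

    def predict_array(self, X: pd.DataFrame) -> np.ndarray:
        self._check_columns(X)
        if self.backend == "lgbm":
            return np.asarray(self.booster.predict(X.to_numpy()), dtype=float)
        import xgboost as xgb

        return np.asarray(
            self.booster.predict(xgb.DMatrix(X.to_numpy())), dtype=float
        )

    def shap_contributions(self, X: pd.DataFrame) -> np.ndarray:
        """Per-row, per-feature TreeSHAP contributions; last column is the
        base (expected) value.  Rows satisfy local accuracy: the row sum
        equals the model prediction."""
        self._check_columns(X)
        if self.backend == "lgbm":
            return np.asarray(
                self.booster.predict(X.to_numpy(), pred_contrib=True), dtype=float
            )
        import xgboost as xgb

        return np.asarray(
            self.booster.predict(xgb.DMatrix(X.to_numpy()), pred_contribs=True),
            dtype=float,
        )

    # ---- persistence -------------------------------------------------

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.model.txt`` (backend-native text format) and
        ``<prefix>.manifest.json``."""
        prefix = Path(prefix)
        model_path = prefix.with_suffix(".model.txt")
        if self.backend == "lgbm":
            model_path.write_text(self.booster.model_to_string())
        else:
            self.booster.save_model(str(prefix.with_suffix(".model.json")))
            model_path = prefix.with_suffix(".model.json")
        prefix.with_suffix(".manifest.json").write_text(
            json.dumps(
                {
                    "backend": self.backend,
                    "params": self.params,
                    "feature_names": self.feature_names,
                    "seed": self.seed,
                    "objective": self.objective,
                    "model_file": model_path.name,
                },
                indent=1,
            )
        )

    @classmethod
    def load(cls, prefix: str | Path) -> "RankModel":
        prefix = Path(prefix)
        manifest = json.loads(prefix.with_suffix(".manifest.json").read_text())
        backend = manifest["backend"]
        model_path = prefix.parent / manifest["model_file"]
        if backend == "lgbm":
            import lightgbm as lgb

            booster = lgb.Booster(model_str=model_path.read_text())
        else:
            import xgboost as xgb

            booster = xgb.Booster()
            booster.load_model(str(model_path))
        return cls(
            backend=backend,
            params=manifest["params"],
            feature_names=manifest["feature_names"],
            seed=manifest["seed"],
            objective=manifest.get("objective", "regression"),
            booster=booster,
        )


def train(
    table: FeatureTable,
    params: Mapping | None = None,
    seed: int = 0,
    backend: Backend = "lgbm",
    objective: Literal["regression", "pairwise"] = "regression",
) -> RankModel:
    """Fit the boosted regression-tree ensemble on the training table.

    Squared-error objective by default; deterministic given ``seed``
    (single-threaded fit).  ``objective='pairwise'`` switches to the
    backend's pairwise ranking loss using the table's query groups.
    """
    if len(table.pairs) < 2:
        raise ValueError("need at least 2 training rows")
    if not np.all(np.isfinite(table.y)):
        raise ValueError("labels must be finite")
    merged = dict(DEFAULT_PARAMS)
    merged.update(params or {})
    n_rounds = int(merged.get("n_estimators", 400))
    X = table.X.to_numpy()
    y = table.y

    group_sizes = None
    if objective == "pairwise":
        if backend == "lgbm":
            raise NotImplementedError(
                "pairwise ranking with continuous affinity labels is only "
                "supported on the 'xgb' backend (LightGBM's lambdarank "
                "requires integer relevance grades)"
            )
        # contiguous query groups required by both backends
        order = np.argsort(table.query.astype(str), kind="stable")
        X, y = X[order], y[order]
        _, counts = np.unique(table.query.astype(str), return_counts=True)
        group_sizes = counts

    if backend == "lgbm":
        import lightgbm as lgb

        dset = lgb.Dataset(
            X, label=y, params={"min_data_in_bin": 1, "verbosity": -1}
        )
        if group_sizes is not None:
            dset.set_group(group_sizes)
        booster = lgb.train(
            _lgbm_params(merged, seed, objective), dset, num_boost_round=n_rounds
        )
    elif backend == "xgb":
        import xgboost as xgb

        dmat = xgb.DMatrix(X, label=y)
        if group_sizes is not None:
            dmat.set_group(group_sizes)
        booster = xgb.train(
            _xgb_params(merged, seed, objective), dmat, num_boost_round=n_rounds
        )
    else:
        raise ValueError(f"unknown backend {backend!r}")

    return RankModel(
        backend=backend,
        params=merged,
        feature_names=table.feature_names,
        seed=seed,
        objective=objective,
        booster=booster,
    )


def predict(model: RankModel, table: FeatureTable) -> pd.DataFrame:
    """Score every row; returns (drug_id, protein_id, query_id, score)."""
    scores = model.predict_array(table.X)
    if not np.all(np.isfinite(scores)):
        raise ValueError("model produced non-finite scores")
    return pd.DataFrame(
        {
            "drug_id": [d for d, _ in table.pairs],
            "protein_id": [p for _, p in table.pairs],
            "query_id": table.query,
            "score": scores,
        }
    )
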