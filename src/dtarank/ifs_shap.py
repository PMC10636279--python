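"""SHAP-driven feature ranking and incremental feature selection (IFS).

Features are ranked by mean absolute SHAP value over the training rows
(TreeSHAP from the fitted boosted-tree backend, checked against the
local-accuracy identity: per-row SHAP values plus the base value sum to
the model prediction).  IFS then retrains the model on nested top-k
subsets in steps of five and evaluates each, producing the
metric-versus-dimension curve from which the smallest "stable" dimension
is read off.

A brute-force Shapley oracle (subset enumeration, absent features
marginalized over an explicit background sample) is provided for small
models; on depth-one stump ensembles it coincides exactly with
path-dependent TreeSHAP.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import factorial
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .features import FeatureTable
from .metrics import EvalReport, evaluate
from .rank_model import RankModel, predict, train

__all__ = [
    "IFSCurve",
    "shap_rank",
    "exact_shapley_oracle",
    "ifs_curve",
    "stable_dim",
]


def shap_values(
    model: RankModel, table: FeatureTable, check_tolerance: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """TreeSHAP contributions (n_rows x n_features) and base values.

    Verifies local accuracy: |sum(shap) + base - prediction| must stay
    within ``check_tolerance`` on every row.
    """
    contrib = model.shap_contributions(table.X)
    phi, base = contrib[:, :-1], contrib[:, -1]
    preds = model.predict_array(table.X)
    gap = np.max(np.abs(phi.sum(axis=1) + base - preds))
    if gap > check_tolerance:
        raise AssertionError(
            f"SHAP local accuracy violated: max |sum(phi)+base-pred| = {gap:g} "
            f"> {check_tolerance:g}"
        )
    return phi, base


def shap_rank(
    model: RankModel, table: FeatureTable, check_tolerance: float = 1e-6
) -> tuple[list[str], dict[str, float]]:
    """Features ordered by descending mean |SHAP| (ties broken by name)."""
    phi, _ = shap_values(model, table, check_tolerance)
    scores = np.abs(phi).mean(axis=0)
    names = model.feature_names
    order = sorted(range(len(names)), key=lambda i: (-scores[i], names[i]))
    ranked = [names[i] for i in order]
    return ranked, {names[i]: float(scores[i]) for i in order}


def exact_shapley_oracle(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    n_features: int | None = None,
) -> np.ndarray:
    """Brute-force Shapley values of one row by subset enumeration.

    The value of a coalition S is the mean prediction over the background
    rows with the features in S taken from ``x`` and the rest from the
    background row (marginalizing absent features over the background
    distribution).  Exponential in the number of features; limited to 10.
    """
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    n = len(x) if n_features is None else n_features
    if n > 10:
        raise ValueError(f"subset enumeration limited to 10 features, got {n}")
    if background.shape[1] != len(x):
        raise ValueError("background width must match the row")

    def value(subset: tuple[int, ...]) -> float:
        rows = background.copy()
        rows[:, list(subset)] = x[list(subset)]
        return float(np.mean(predict_fn(rows)))

    cache: dict[tuple[int, ...], float] = {}

    def v(subset: frozenset[int]) -> float:
        key = tuple(sorted(subset))
        if key not in cache:
            cache[key] = value(key)
        return cache[key]

    phi = np.zeros(n)
    all_features = set(range(n))
    for i in range(n):
        others = sorted(all_features - {i})
        for size in range(len(others) + 1):
            w = factorial(size) * factorial(n - size - 1) / factorial(n)
            for S in combinations(others, size):
                phi[i] += w * (v(frozenset(S) | {i}) - v(frozenset(S)))
    return phi


@dataclass
class IFSCurve:
    """Metric values along nested SHAP-ranked feature subsets."""

    dims: list[int]
    reports: list[EvalReport]
    ranking: list[str]
    scores: dict[str, float] = field(default_factory=dict)
    tolerance: float = 0.005

    def __post_init__(self) -> None:
        if len(self.dims) != len(self.reports):
            raise ValueError("dims and reports must have equal length")
        if any(b <= a for a, b in zip(self.dims, self.dims[1:])):
            raise ValueError("dims must be strictly increasing")

    @property
    def stable_dim(self) -> int:
        return stable_dim(self, self.tolerance)

    def to_files(self, prefix: str | Path) -> None:
        """Write ``<prefix>.tsv`` (dim, ci, mse, rm2) and ``<prefix>.json``
        (ranking, scores, stable_dim)."""
        prefix = Path(prefix)
        lines = ["dim\tci\tmse\trm2"]
        for d, r in zip(self.dims, self.reports):
            lines.append(f"{d}\t{r.ci:.6f}\t{r.mse:.6f}\t{r.rm2:.6f}")
        prefix.with_suffix(".tsv").write_text("\n".join(lines) + "\n")
        prefix.with_suffix(".json").write_text(
            json.dumps(
                {
                    "ranking": self.ranking,
                    "scores": self.scores,
                    "stable_dim": self.stable_dim,
                    "tolerance": self.tolerance,
                },
                indent=1,
            )
        )

    def plot(self, path: str | Path) -> None:
        """Metric-versus-dimension curves (CI, MSE, rm2) to an image file."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(self.dims, [r.ci for r in self.reports], marker="o", label="CI")
        ax.plot(self.dims, [r.mse for r in self.reports], marker="s", label="MSE")
        ax.plot(self.dims, [r.rm2 for r in self.reports], marker="^", label="rm2")
        ax.axvline(self.stable_dim, ls="--", color="gray",
                   label=f"stable dim = {self.stable_dim}")
        ax.set_xlabel("feature dimension")
        ax.set_ylabel("metric value")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def ifs_curve(
    train_table: FeatureTable,
    test_table: FeatureTable,
    ranking: Sequence[str],
    step: int = 5,
    model_params: Mapping | None = None,
    seed: int = 0,
    backend: str = "lgbm",
    scores: Mapping[str, float] | None = None,
    mode: str = "global",
    tolerance: float = 0.005,
) -> IFSCurve:
    """Retrain on nested top-k prefixes of ``ranking`` (k = step, 2*step,
    ..., full dimension) with fixed hyperparameters and seed; evaluate each
    on the test rows."""
    if step <= 0:
        raise ValueError("step must be positive")
    ranking = list(ranking)
    if set(ranking) != set(train_table.feature_names):
        raise ValueError("ranking must cover exactly the table's columns")
    full = len(ranking)
    dims = list(range(step, full, step))
    if not dims or dims[-1] != full:
        dims.append(full)

    reports = []
    for k in dims:
        cols = ranking[:k]
        model = train(
            train_table.subset_columns(cols),
            params=model_params,
            seed=seed,
            backend=backend,  # type: ignore[arg-type]
        )
        sub_test = test_table.subset_columns(cols)
        scored = predict(model, sub_test)
        reports.append(
            evaluate(sub_test.y, scored["score"].to_numpy(), sub_test.query,
                     mode=mode)  # type: ignore[arg-type]
        )
    return IFSCurve(
        dims=dims,
        reports=reports,
        ranking=ranking,
        scores=dict(scores or {}),
        tolerance=tolerance,
    )


def stable_dim(curve: IFSCurve, tolerance: float = 0.005) -> int:
    """Smallest dimension whose CI — and every later CI — stays within
    ``tolerance`` of the full-dimension CI; falls back to the full
    dimension."""
    cis = [r.ci for r in curve.reports]
    final = cis[-1]
    for i, d in enumerate(curve.dims):
        if all(abs(c - final) <= tolerance for c in cis[i:]):
            return d
    return curve.dims[-1]
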