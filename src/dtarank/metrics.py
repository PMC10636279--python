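"""Evaluation metrics for affinity regression-and-ranking: concordance
index (CI), mean squared error (MSE) and Roy's rm2, with optional
per-query aggregation.

CI is the probability-like statistic that, for a random pair of examples
with different labels, the one with the higher label also gets the higher
score; score ties count one half.  rm2 = r^2 * (1 - sqrt(r^2 - r0^2))
penalizes divergence between the ordinary least-squares fit and the fit
forced through the origin; it is the external-validation statistic
customarily reported alongside CI on affinity benchmarks.  Note rm2 is not
symmetric in its arguments: labels come first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = ["EvalReport", "concordance_index", "mse", "rm2", "evaluate"]


@dataclass
class EvalReport:
    ci: float
    mse: float
    rm2: float
    mode: Literal["global", "per-query-mean"]
    n_pairs: int
    n_queries: int
    n_queries_skipped: int = 0

    def as_dict(self) -> dict:
        return {
            "ci": self.ci,
            "mse": self.mse,
            "rm2": self.rm2,
            "mode": self.mode,
            "n_pairs": self.n_pairs,
            "n_queries": self.n_queries,
            "n_queries_skipped": self.n_queries_skipped,
        }


class _Fenwick:
    """Binary indexed tree over score ranks for O(n log n) pair counting."""

    def __init__(self, n: int) -> None:
        self.tree = [0] * (n + 1)

    def add(self, i: int) -> None:
        i += 1
        while i < len(self.tree):
            self.tree[i] += 1
            i += i & (-i)

    def prefix(self, i: int) -> int:
        """Count of inserted ranks <= i."""
        i += 1
        s = 0
        while i > 0:
            s += self.tree[i]
            i -= i & (-i)
        return s


def concordance_index(y, s) -> float:
    """Concordance index over all label-discordant pairs, ties in the score
    counting 0.5.  O(n log n); agrees exactly with the quadratic
    definition."""
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("y and s must be 1-D arrays of equal length")
    if len(y) < 2:
        raise ValueError("need at least two examples")

    # compress scores to dense ranks
    order = np.argsort(y, kind="stable")
    ranks = {v: r for r, v in enumerate(np.unique(s))}
    tree = _Fenwick(len(ranks))

    concordant = 0  # earlier (smaller label) element had smaller score
    tied = 0
    comparable = 0
    seen = 0
    i = 0
    ys, ss = y[order], s[order]
    n = len(ys)
    while i < n:
        j = i
        while j < n and ys[j] == ys[i]:
            j += 1
        # elements i..j-1 share a label: compare against all previously
        # inserted (strictly smaller label) elements
        for k in range(i, j):
            r = ranks[ss[k]]
            below_or_eq = tree.prefix(r)
            eq = below_or_eq - (tree.prefix(r - 1) if r > 0 else 0)
            concordant += below_or_eq - eq
            tied += eq
            comparable += seen
        for k in range(i, j):
            tree.add(ranks[ss[k]])
        seen += j - i
        i = j
    if comparable == 0:
        raise ValueError("concordance index undefined: all labels are tied")
    return (2 * concordant + tied) / (2 * comparable)


def mse(y, s) -> float:
    """Mean squared error."""
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    if y.shape != s.shape or len(y) < 1:
        raise ValueError("y and s must be non-empty arrays of equal length")
    return float(np.mean((y - s) ** 2))


def rm2(y, s) -> float:
    """Roy's modified squared correlation, rm2 = r^2 (1 - sqrt(r^2 - r0^2)).

    r^2 is the squared Pearson correlation of labels and scores; r0^2 the
    coefficient of determination of the least-squares fit of y on s forced
    through the origin (slope k = sum(y s) / sum(s^2)).  The difference
    r^2 - r0^2 is clipped at zero against floating-point jitter.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    if y.shape != s.shape or len(y) < 2:
        raise ValueError("y and s must be arrays of equal length >= 2")
    if np.var(y) == 0 or np.var(s) == 0:
        raise ValueError("rm2 undefined for zero-variance input")
    r = np.corrcoef(y, s)[0, 1]
    r2 = r * r
    k = float(np.sum(y * s) / np.sum(s * s))
    ss_res0 = float(np.sum((y - k * s) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r02 = 1.0 - ss_res0 / ss_tot
    return float(r2 * (1.0 - np.sqrt(max(r2 - r02, 0.0))))


def evaluate(
    y,
    s,
    query=None,
    mode: Literal["global", "per-query-mean"] = "global",
) -> EvalReport:
    """Pool all pairs (global) or average CI over queries (per-query-mean).

    In per-query mode the CI is computed within each query having at least
    two distinct labels and averaged; queries without a defined CI are
    counted as skipped.  MSE and rm2 are always pooled.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    query = (
        np.zeros(len(y), dtype=object)
        if query is None
        else np.asarray(query, dtype=object)
    )
    if not (len(y) == len(s) == len(query)):
        raise ValueError("y, s and query must have equal length")
    queries = list(dict.fromkeys(query))
    pooled_mse = mse(y, s)
    pooled_rm2 = rm2(y, s)
    if mode == "global":
        return EvalReport(
            ci=concordance_index(y, s),
            mse=pooled_mse,
            rm2=pooled_rm2,
            mode="global",
            n_pairs=len(y),
            n_queries=len(queries),
        )
    if mode != "per-query-mean":
        raise ValueError(f"unknown mode {mode!r}")
    cis = []
    skipped = 0
    for q in queries:
        m = query == q
        if len(np.unique(y[m])) < 2:
            skipped += 1
            continue
        cis.append(concordance_index(y[m], s[m]))
    if not cis:
        raise ValueError("no query has two distinct labels; per-query CI undefined")
    return EvalReport(
        ci=float(np.mean(cis)),
        mse=pooled_mse,
        rm2=pooled_rm2,
        mode="per-query-mean",
        n_pairs=len(y),
        n_queries=len(queries),
        n_queries_skipped=skipped,
    )
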