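"""Core matrix containers, delimited-text I/O, sharing-matrix derivation and
cold-start scenario splitting.

The central object is a drug x protein affinity matrix (pKd-like or
KIBA-like scores) with an explicit observed mask: sparse benchmarks leave
most drug-protein pairs unmeasured, and every downstream statistic must be
computed on observed entries only.  Entity-by-entity similarity matrices
(chemical-structure similarity for drugs, normalized Smith-Waterman for
proteins) are inputs; sharing matrices (counts of common binding partners
above an activity threshold) are derived here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AffinityMatrix",
    "SimilarityMatrix",
    "SharingMatrix",
    "ScenarioSplit",
    "MatrixValidationError",
    "load_matrix",
    "save_matrix",
    "compute_sharing",
    "make_split",
    "PKD_ACTIVE_THRESHOLD",
    "KIBA_ACTIVE_THRESHOLD",
]

#: Conventional activity cutoffs used to binarize continuous affinities when
#: counting shared binding partners: pKd >= 7 (Kd <= 100 nM) and the
#: customary KIBA-score cutoff of 12.1.
PKD_ACTIVE_THRESHOLD = 7.0
KIBA_ACTIVE_THRESHOLD = 12.1

MISSING_TOKENS = ("", "NA")


class MatrixValidationError(ValueError):
    """Raised when an input matrix violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise MatrixValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)
    return ids


@dataclass
class AffinityMatrix:
    """Real-valued drug x protein affinity scores with an observed mask."""

    drug_ids: list[str]
    protein_ids: list[str]
    values: np.ndarray  # shape (n_drugs, n_proteins), float
    observed: np.ndarray  # same shape, bool

    def __post_init__(self) -> None:
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.protein_ids = _check_unique(self.protein_ids, "protein")
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        shape = (len(self.drug_ids), len(self.protein_ids))
        if self.values.shape != shape:
            raise MatrixValidationError(
                f"affinity values shape {self.values.shape} != {shape}"
            )
        if self.observed.shape != shape:
            raise MatrixValidationError(
                f"observed mask shape {self.observed.shape} != {shape}"
            )
        if not np.all(np.isfinite(self.values[self.observed])):
            raise MatrixValidationError("observed affinities must be finite")

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    def drug_index(self, drug_id: str) -> int:
        return self.drug_ids.index(drug_id)

    def protein_index(self, protein_id: str) -> int:
        return self.protein_ids.index(protein_id)

    def observed_pairs(self) -> list[tuple[str, str]]:
        """All (drug_id, protein_id) pairs with a measured affinity."""
        di, pi = np.nonzero(self.observed)
        return [(self.drug_ids[d], self.protein_ids[p]) for d, p in zip(di, pi)]

    def restrict_to_pairs(self, pairs: Sequence[tuple[str, str]]) -> "AffinityMatrix":
        """Copy with the observed mask restricted to ``pairs`` only.

        Used to build a training-only view of the affinity matrix so that
        held-out labels can never reach feature computations.
        """
        mask = np.zeros_like(self.observed)
        dmap = {d: i for i, d in enumerate(self.drug_ids)}
        pmap = {p: i for i, p in enumerate(self.protein_ids)}
        for d, p in pairs:
            mask[dmap[d], pmap[p]] = True
        if not np.all(self.observed[mask]):
            raise MatrixValidationError("pair list references an unobserved cell")
        return AffinityMatrix(
            list(self.drug_ids), list(self.protein_ids), self.values.copy(), mask
        )


@dataclass
class SimilarityMatrix:
    """Square symmetric entity similarity in [0, 1] with unit diagonal."""

    entity_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.entity_ids = _check_unique(self.entity_ids, "entity")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise MatrixValidationError(
                f"similarity matrix must be square {n}x{n}, got {self.values.shape}"
            )
        asym = np.abs(self.values - self.values.T)
        if asym.size and asym.max() > 1e-9:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise MatrixValidationError(
                "similarity matrix not symmetric: first offending cell "
                f"({self.entity_ids[i]}, {self.entity_ids[j]}) "
                f"{self.values[i, j]!r} vs {self.values[j, i]!r}"
            )
        bad = (self.values < 0) | (self.values > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixValidationError(
                f"similarity out of [0,1] at ({self.entity_ids[i]}, "
                f"{self.entity_ids[j]}): {self.values[i, j]!r}"
            )
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            i = int(np.argmax(np.abs(np.diag(self.values) - 1.0)))
            raise MatrixValidationError(
                f"similarity diagonal must be 1.0; entity {self.entity_ids[i]} "
                f"has {self.values[i, i]!r}"
            )

    def index(self, entity_id: str) -> int:
        return self.entity_ids.index(entity_id)

    def row(self, entity_id: str) -> np.ndarray:
        return self.values[self.index(entity_id)]


@dataclass
class SharingMatrix:
    """Counts of common binding partners between entities of one side.

    ``values[i, j]`` is the number of counterpart entities whose observed
    affinity with both *i* and *j* meets the activity threshold used at
    derivation time.  The diagonal holds each entity's own partner count
    (bookkeeping only; never used as a feature input).
    """

    entity_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.entity_ids = _check_unique(self.entity_ids, "entity")
        self.values = np.asarray(self.values)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise MatrixValidationError("sharing matrix must be square")
        if not np.array_equal(self.values, self.values.T):
            raise MatrixValidationError("sharing matrix must be symmetric")
        if (self.values < 0).any():
            raise MatrixValidationError("sharing counts must be >= 0")
        self.values = self.values.astype(int)

    def index(self, entity_id: str) -> int:
        return self.entity_ids.index(entity_id)

    def row(self, entity_id: str) -> np.ndarray:
        return self.values[self.index(entity_id)]


Scenario = Literal["S1", "S2"]


@dataclass
class ScenarioSplit:
    """Cold-entity train/test split with learning-to-rank query assignment.

    S1 holds out whole drugs ("new drugs", proteins act as queries); S2
    holds out whole proteins ("new proteins", drugs act as queries).
    """

    scenario: Scenario
    train_pairs: list[tuple[str, str]]
    test_pairs: list[tuple[str, str]]
    seed: int
    test_fraction: float = 0.0
    query_of: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in ("S1", "S2"):
            raise ValueError(f"scenario must be 'S1' or 'S2', got {self.scenario!r}")
        if not self.query_of:
            qi = 1 if self.scenario == "S1" else 0
            self.query_of = {
                pair: pair[qi] for pair in self.train_pairs + self.test_pairs
            }
        overlap = set(self.train_pairs) & set(self.test_pairs)
        if overlap:
            raise ValueError(f"train/test pair overlap: {sorted(overlap)[:3]}")
        cold = 0 if self.scenario == "S1" else 1
        train_cold = {p[cold] for p in self.train_pairs}
        test_cold = {p[cold] for p in self.test_pairs}
        if train_cold & test_cold:
            raise ValueError(
                "cold-side entities appear on both sides of the split: "
                f"{sorted(train_cold & test_cold)[:3]}"
            )

    @property
    def train_queries(self) -> list[str]:
        return sorted({self.query_of[p] for p in self.train_pairs})

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scenario": self.scenario,
            "seed": self.seed,
            "test_fraction": self.test_fraction,
            "train_pairs": [list(p) for p in self.train_pairs],
            "test_pairs": [list(p) for p in self.test_pairs],
            "query_of": {f"{d}\t{p}": q for (d, p), q in self.query_of.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioSplit":
        payload = json.loads(Path(path).read_text())
        return cls(
            scenario=payload["scenario"],
            train_pairs=[tuple(p) for p in payload["train_pairs"]],
            test_pairs=[tuple(p) for p in payload["test_pairs"]],
            seed=payload["seed"],
            test_fraction=payload.get("test_fraction", 0.0),
            query_of={
                tuple(k.split("\t")): v for k, v in payload["query_of"].items()
            },
        )


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    _check_unique(header, "column")  # pandas would silently mangle duplicates
    return pd.read_csv(
        path,
        sep=sep,
        index_col=0,
        na_values=list(MISSING_TOKENS),
        keep_default_na=False,
        dtype=str,
    )


def load_matrix(
    path: str | Path,
    kind: Literal["affinity", "similarity"],
    missing_tokens: Sequence[str] = MISSING_TOKENS,
) -> AffinityMatrix | SimilarityMatrix:
    """Read a delimited-text matrix (CSV/TSV chosen by extension).

    The file must have a header row of column ids and a first column of row
    ids.  For ``kind='affinity'`` empty cells or any ``missing_tokens`` mark
    unobserved pairs; for ``kind='similarity'`` missing values are an error.
    """
    df = _read_frame(path)
    raw = df.to_numpy()
    missing = pd.isna(df).to_numpy()
    for tok in missing_tokens:
        if tok:
            missing |= raw == tok
    values = np.full(df.shape, np.nan)
    ok = ~missing
    values[ok] = pd.to_numeric(pd.Series(raw[ok].ravel())).to_numpy()

    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if kind == "affinity":
        out = values.copy()
        out[missing] = np.nan
        return AffinityMatrix(row_ids, col_ids, np.nan_to_num(out), ~missing)
    if kind == "similarity":
        if missing.any():
            i, j = np.argwhere(missing)[0]
            raise MatrixValidationError(
                f"similarity matrix has a missing value at ({row_ids[i]}, {col_ids[j]})"
            )
        if row_ids != col_ids:
            raise MatrixValidationError(
                "similarity matrix row and column ids differ (non-square input)"
            )
        return SimilarityMatrix(row_ids, values)
    raise ValueError(f"unknown matrix kind {kind!r}")


def save_matrix(
    matrix: AffinityMatrix | SimilarityMatrix | SharingMatrix,
    path: str | Path,
    float_format: str = "%.10g",
) -> None:
    """Write a matrix as delimited text (CSV or TSV by extension).

    Unobserved affinity cells are written empty, so a save/load round trip
    preserves the observed mask.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    if isinstance(matrix, AffinityMatrix):
        vals = matrix.values.astype(object)
        vals[~matrix.observed] = np.nan
        df = pd.DataFrame(vals, index=matrix.drug_ids, columns=matrix.protein_ids)
    else:
        df = pd.DataFrame(
            matrix.values, index=matrix.entity_ids, columns=matrix.entity_ids
        )
    df.to_csv(path, sep=sep, float_format=float_format, na_rep="")


def compute_sharing(
    affinity: AffinityMatrix,
    side: Literal["drug", "protein"],
    binarize_threshold: float = PKD_ACTIVE_THRESHOLD,
) -> SharingMatrix:
    """Count shared active binding partners between entities of one side.

    Continuous affinities are binarized at ``binarize_threshold``: a
    counterpart counts as a partner when its observed affinity meets or
    exceeds the threshold.  ``sharing(i, j)`` is then the number of
    counterparts active for both *i* and *j*.
    """
    active = affinity.observed & (affinity.values >= binarize_threshold)
    if side == "drug":
        b = active.astype(int)  # drugs x proteins
        ids = affinity.drug_ids
    elif side == "protein":
        b = active.T.astype(int)  # proteins x drugs
        ids = affinity.protein_ids
    else:
        raise ValueError(f"side must be 'drug' or 'protein', got {side!r}")
    counts = b @ b.T
    return SharingMatrix(list(ids), counts)


def make_split(
    affinity: AffinityMatrix,
    scenario: Scenario,
    test_fraction: float,
    seed: int,
) -> ScenarioSplit:
    """Cold-entity split: all observed pairs of held-out entities go to test.

    Cold-side entities (drugs for S1, proteins for S2) are partitioned
    uniformly at random; queries are the warm-side ids.  Deterministic given
    ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    cold_ids = affinity.drug_ids if scenario == "S1" else affinity.protein_ids
    n = len(cold_ids)
    n_test = int(round(test_fraction * n))
    if n_test == 0 or n_test == n:
        raise ValueError(
            f"test_fraction {test_fraction} leaves {n_test} of {n} cold-side "
            "entities in test; need at least one on each side"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_set = {cold_ids[i] for i in perm[:n_test]}

    cold = 0 if scenario == "S1" else 1
    train_pairs, test_pairs = [], []
    for pair in affinity.observed_pairs():
        (test_pairs if pair[cold] in test_set else train_pairs).append(pair)
    return ScenarioSplit(
        scenario=scenario,
        train_pairs=train_pairs,
        test_pairs=test_pairs,
        seed=seed,
        test_fraction=test_fraction,
    )
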