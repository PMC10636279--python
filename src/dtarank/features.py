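"""Similarity/sharing/affinity-profile feature engineering.

Every drug and every protein is described by 22 *self-associated features*
(SAF): five order statistics of its similarity profile, sixteen statistics
of its observed affinity profile, and the mean of its affinity row.
*Adjacent-associated features* (AAF) are the same 22 statistics aggregated
over an entity's neighbors in a similarity or sharing graph, under two
neighbor-selection schemes (fixed threshold, or top-5 plus each of their
top-5).  A drug-protein pair is represented by the concatenation of the
drug's SAF and AAF blocks with the protein's.

Leakage control: all affinity-profile statistics are computed from
*training* pairs only, and for a training pair the pair's own label is
masked before computing that pair's profile statistics.  Cold entities
(e.g. new drugs in the cold-drug scenario) have no training affinities;
their profile statistics take a cold-start fill value (the global training
mean affinity) and their information is carried by the AAF blocks.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    AffinityMatrix,
    ScenarioSplit,
    SharingMatrix,
    SimilarityMatrix,
)

__all__ = [
    "SAF_STAT_NAMES",
    "SAFVector",
    "NeighborSet",
    "FeatureTable",
    "BlockConfig",
    "extract_saf",
    "select_neighbors_threshold",
    "select_neighbors_top5exp",
    "aggregate_aaf",
    "build_feature_table",
]

logger = logging.getLogger(__name__)

#: The 22 per-entity statistics, in canonical order: similarity-profile
#: order statistics, affinity-profile statistics, five highest / five
#: lowest observed affinities, and the affinity-row mean.
SAF_STAT_NAMES: tuple[str, ...] = (
    "sim_mean",
    "sim_p50",
    "sim_p75",
    "sim_p85",
    "sim_p95",
    "aff_mean",
    "aff_count",
    "aff_mode",
    "aff_p25",
    "aff_p50",
    "aff_p75",
    "aff_top1",
    "aff_top2",
    "aff_top3",
    "aff_top4",
    "aff_top5",
    "aff_low1",
    "aff_low2",
    "aff_low3",
    "aff_low4",
    "aff_low5",
    "aff_row_mean",
)

N_SAF = len(SAF_STAT_NAMES)  # 22


@dataclass
class SAFVector:
    """The 22 self-associated statistics of one entity."""

    entity_id: str
    side: Literal["drug", "protein"]
    values: np.ndarray  # length 22, ordered as SAF_STAT_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_SAF,):
            raise ValueError(f"SAF vector must have {N_SAF} entries")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(SAF_STAT_NAMES, self.values))


@dataclass
class NeighborSet:
    """Ordered neighbors of one entity under one selection scheme."""

    entity_id: str
    neighbor_ids: list[str]
    scheme: Literal["threshold", "top5exp"]
    source: Literal["similarity", "sharing"]
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.entity_id in self.neighbor_ids:
            raise ValueError("an entity cannot be its own neighbor")


def _mode_rounded(profile: np.ndarray, decimals: int = 2) -> float:
    """Most frequent value after rounding; ties resolved to the smallest."""
    rounded = np.round(profile, decimals)
    uniq, counts = np.unique(rounded, return_counts=True)
    return float(uniq[np.argmax(counts)])  # uniq sorted -> first max is smallest


def _pad_order_stats(sorted_vals: np.ndarray, k: int = 5) -> np.ndarray:
    """First ``k`` of ``sorted_vals``, repeating the last available entry."""
    if len(sorted_vals) >= k:
        return sorted_vals[:k]
    return np.concatenate([sorted_vals, np.full(k - len(sorted_vals), sorted_vals[-1])])


def affinity_profile_stats(profile: np.ndarray, cold_fill: float) -> np.ndarray:
    """The 17 affinity-derived statistics (mean..row-mean) of one profile.

    ``profile`` holds the entity's *observed* affinities only.  An empty
    profile yields the cold-start fill everywhere except the count, which
    is 0.
    """
    out = np.empty(17)
    if len(profile) == 0:
        out.fill(cold_fill)
        out[1] = 0.0
        return out
    out[0] = profile.mean()
    out[1] = float(len(profile))
    out[2] = _mode_rounded(profile)
    out[3:6] = np.percentile(profile, [25, 50, 75])
    desc = np.sort(profile)[::-1]
    out[6:11] = _pad_order_stats(desc)
    out[11:16] = _pad_order_stats(desc[::-1])
    out[16] = profile.mean()  # affinity-row mean over observed entries
    return out


def extract_saf(
    entity: str,
    side: Literal["drug", "protein"],
    similarity: SimilarityMatrix,
    affinity: AffinityMatrix,
    exclude_pair: str | None = None,
    cold_fill: float | None = None,
) -> SAFVector:
    """Compute the 22 self-associated statistics of one entity.

    The similarity profile excludes the self-similarity diagonal.  The
    affinity profile uses observed entries only; ``exclude_pair`` (a
    counterpart id) masks that single cell first — the leakage control for
    a training pair's own label.  Entities with no observed affinities get
    ``cold_fill`` (default: mean of the observed affinities in ``affinity``)
    in every affinity-derived statistic, with count 0.
    """
    i = similarity.index(entity)
    sim_profile = np.delete(similarity.values[i], i)

    if side == "drug":
        r = affinity.drug_index(entity)
        vals, obs = affinity.values[r], affinity.observed[r].copy()
        if exclude_pair is not None:
            obs[affinity.protein_index(exclude_pair)] = False
    else:
        c = affinity.protein_index(entity)
        vals, obs = affinity.values[:, c], affinity.observed[:, c].copy()
        if exclude_pair is not None:
            obs[affinity.drug_index(exclude_pair)] = False
    profile = vals[obs]

    if cold_fill is None:
        observed_all = affinity.values[affinity.observed]
        cold_fill = float(observed_all.mean()) if observed_all.size else 0.0

    out = np.empty(N_SAF)
    out[0] = sim_profile.mean()
    out[1:5] = np.percentile(sim_profile, [50, 75, 85, 95])
    out[5:] = affinity_profile_stats(profile, cold_fill)
    return SAFVector(entity, side, out)


def _ordered_by_value(
    ids: Sequence[str], values: np.ndarray, candidates: np.ndarray
) -> list[str]:
    """Candidate indices sorted by descending value, ties by id."""
    cand = [(float(-values[j]), str(ids[j])) for j in candidates]
    return [eid for _, eid in sorted(cand)]


def select_neighbors_threshold(
    matrix: SimilarityMatrix | SharingMatrix,
    entity: str,
    threshold: float,
) -> NeighborSet:
    """Neighbors whose similarity/sharing with ``entity`` strictly exceeds
    ``threshold``, ordered by descending value (ties by id)."""
    i = matrix.index(entity)
    row = np.asarray(matrix.values[i], dtype=float)
    cand = np.flatnonzero(row > threshold)
    cand = cand[cand != i]
    return NeighborSet(
        entity_id=entity,
        neighbor_ids=_ordered_by_value(matrix.entity_ids, row, cand),
        scheme="threshold",
        source="similarity" if isinstance(matrix, SimilarityMatrix) else "sharing",
        threshold=threshold,
    )


def _top_k(similarity: SimilarityMatrix, i: int, k: int) -> list[str]:
    row = similarity.values[i].copy()
    cand = np.delete(np.arange(len(row)), i)
    ordered = _ordered_by_value(similarity.entity_ids, row, cand)
    return ordered[:k]


def select_neighbors_top5exp(
    similarity: SimilarityMatrix, entity: str, k: int = 5
) -> NeighborSet:
    """Two-tier neighbor expansion: the top-5 most similar entities, plus
    each of their own top-5, deduplicated (self removed, first occurrence
    kept)."""
    n = len(similarity.entity_ids)
    i = similarity.index(entity)
    if n < k + 1:
        logger.warning(
            "top5exp: matrix has only %d entities; returning all non-self", n
        )
        warnings.warn(
            f"top5exp neighbor expansion needs >= {k + 1} entities, got {n}; "
            "returning all non-self entities",
            stacklevel=2,
        )
        tier1 = _top_k(similarity, i, n - 1)
        return NeighborSet(entity, tier1, "top5exp", "similarity")

    tier1 = _top_k(similarity, i, k)
    ordered: list[str] = list(tier1)
    seen = set(tier1) | {entity}
    for nb in tier1:
        for nb2 in _top_k(similarity, similarity.index(nb), k):
            if nb2 not in seen:
                ordered.append(nb2)
                seen.add(nb2)
    return NeighborSet(entity, ordered, "top5exp", "similarity")


def aggregate_aaf(
    neighbors: NeighborSet,
    saf_of: Mapping[str, SAFVector],
    weights: Literal["none", "similarity"] = "none",
    similarity: SimilarityMatrix | SharingMatrix | None = None,
    cold_fill: float = 0.0,
) -> np.ndarray:
    """Component-wise aggregate of the neighbors' SAF vectors (22 values).

    Unweighted mean by default; ``weights='similarity'`` weights each
    neighbor by its matrix value with the entity.  An empty neighbor set
    yields the cold-start fill in every component.
    """
    if not neighbors.neighbor_ids:
        return np.full(N_SAF, cold_fill)
    stack = np.stack([saf_of[nb].values for nb in neighbors.neighbor_ids])
    if weights == "none":
        return stack.mean(axis=0)
    if weights == "similarity":
        if similarity is None:
            raise ValueError("similarity weighting requires the source matrix")
        i = similarity.index(neighbors.entity_id)
        w = np.array(
            [float(similarity.values[i, similarity.index(nb)])
             for nb in neighbors.neighbor_ids]
        )
        if w.sum() <= 0:
            return stack.mean(axis=0)
        return (w[:, None] * stack).sum(axis=0) / w.sum()
    raise ValueError(f"unknown weighting {weights!r}")


@dataclass
class BlockConfig:
    """Which AAF blocks to build per side.

    ``sim_thresholds`` / ``sharing_thresholds`` each define one
    threshold-scheme AAF block per value; ``top5exp`` adds the two-tier
    expansion block on the similarity matrix.  ``sharing_binarize_threshold``
    is the activity cutoff used when deriving sharing matrices (pKd-style
    default 7.0).
    """

    sim_thresholds: tuple[float, ...] = (0.3, 0.5, 0.7)
    sharing_thresholds: tuple[float, ...] = (1.0, 3.0)
    top5exp: bool = True
    aggregation: Literal["none", "similarity"] = "none"
    sharing_binarize_threshold: float = 7.0

    def n_aaf_blocks(self) -> int:
        return (
            len(self.sim_thresholds)
            + len(self.sharing_thresholds)
            + (1 if self.top5exp else 0)
        )

    def n_columns(self) -> int:
        """Total feature-table width: 2 sides x 22 x (SAF + AAF blocks)."""
        return 2 * N_SAF * (1 + self.n_aaf_blocks())

    def validate(self) -> None:
        if self.n_aaf_blocks() == 0:
            raise ValueError("block configuration defines no AAF blocks")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "sim_thresholds": list(self.sim_thresholds),
                    "sharing_thresholds": list(self.sharing_thresholds),
                    "top5exp": self.top5exp,
                    "aggregation": self.aggregation,
                    "sharing_binarize_threshold": self.sharing_binarize_threshold,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "BlockConfig":
        d = json.loads(Path(path).read_text())
        return cls(
            sim_thresholds=tuple(d["sim_thresholds"]),
            sharing_thresholds=tuple(d["sharing_thresholds"]),
            top5exp=d["top5exp"],
            aggregation=d.get("aggregation", "none"),
            sharing_binarize_threshold=d.get("sharing_binarize_threshold", 7.0),
        )


@dataclass
class FeatureTable:
    """Per-pair feature rows with labels, query ids and column provenance."""

    pairs: list[tuple[str, str]]
    X: pd.DataFrame  # one row per pair, named feature columns
    y: np.ndarray  # affinity labels
    query: np.ndarray  # query id per pair (protein in S1, drug in S2)
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.query = np.asarray(self.query, dtype=object)
        if not (len(self.pairs) == len(self.X) == len(self.y) == len(self.query)):
            raise ValueError("pairs, X, y and query must have equal length")
        if self.X.columns.duplicated().any():
            raise ValueError("feature column names must be unique")
        if self.X.isna().any().any():
            bad = self.X.columns[self.X.isna().any()][0]
            raise ValueError(f"feature column {bad!r} contains missing values")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset_columns(self, names: Sequence[str]) -> "FeatureTable":
        return FeatureTable(
            list(self.pairs),
            self.X[list(names)].copy(),
            self.y.copy(),
            self.query.copy(),
            {k: v for k, v in self.provenance.items() if k in set(names)},
        )

    # ---- persistence -------------------------------------------------

    def to_files(self, prefix: str | Path) -> None:
        """Write ``<prefix>.tsv`` (pairs, query, label, features) and a JSON
        provenance sidecar ``<prefix>.provenance.json``."""
        prefix = Path(prefix)
        df = self.X.copy()
        df.insert(0, "drug_id", [d for d, _ in self.pairs])
        df.insert(1, "protein_id", [p for _, p in self.pairs])
        df.insert(2, "query_id", self.query)
        df.insert(3, "label", self.y)
        df.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False,
                  float_format="%.12g")
        prefix.with_suffix(".provenance.json").write_text(
            json.dumps(self.provenance, indent=1)
        )

    @classmethod
    def from_files(cls, prefix: str | Path) -> "FeatureTable":
        prefix = Path(prefix)
        df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
        pairs = list(zip(df.pop("drug_id").astype(str), df.pop("protein_id").astype(str)))
        query = df.pop("query_id").astype(str).to_numpy()
        y = df.pop("label").to_numpy(dtype=float)
        prov_path = prefix.with_suffix(".provenance.json")
        prov = json.loads(prov_path.read_text()) if prov_path.exists() else {}
        return cls(pairs, df, y, query, prov)

    def to_svmlight(self, path: str | Path) -> None:
        """SVMlight-with-qid export: ``label qid:<q> 1:<v> 2:<v> ...``.

        Query ids are mapped to dense integers in first-appearance order; a
        ``<path>.queries.json`` sidecar records the mapping.
        """
        qmap: dict[str, int] = {}
        lines = []
        for row, label, q in zip(self.X.to_numpy(), self.y, self.query):
            qi = qmap.setdefault(str(q), len(qmap) + 1)
            feats = " ".join(f"{j + 1}:{v:.12g}" for j, v in enumerate(row))
            lines.append(f"{label:.12g} qid:{qi} {feats}")
        Path(path).write_text("\n".join(lines) + "\n")
        Path(f"{path}.queries.json").write_text(json.dumps(qmap, indent=1))


def _provenance(side: str, block: str, source: str, scheme: str,
                threshold: float | None, stat: str) -> dict:
    return {
        "side": side,
        "block": block,
        "source": source,
        "scheme": scheme,
        "threshold": threshold,
        "statistic": stat,
    }


def build_feature_table(
    split: ScenarioSplit,
    drug_similarity: SimilarityMatrix,
    protein_similarity: SimilarityMatrix,
    affinity: AffinityMatrix,
    config: BlockConfig | None = None,
) -> tuple[FeatureTable, FeatureTable]:
    """Assemble train and test feature tables for one scenario split.

    Sharing matrices, all profile statistics and all neighbor sets are
    derived from the *training* pairs' affinities only; for each training
    pair the pair's own label is additionally masked when computing that
    row's profile statistics.  Test labels are carried through for
    evaluation but are never read during feature construction.
    """
    from .data_model import compute_sharing  # local to avoid cycle at import

    config = config or BlockConfig()
    config.validate()
    if config.n_aaf_blocks() == 0:
        raise ValueError("block configuration defines no AAF blocks")

    train_affinity = affinity.restrict_to_pairs(split.train_pairs)
    observed_train = train_affinity.values[train_affinity.observed]
    cold_fill = float(observed_train.mean())

    drug_sharing = compute_sharing(
        train_affinity, "drug", config.sharing_binarize_threshold
    )
    prot_sharing = compute_sharing(
        train_affinity, "protein", config.sharing_binarize_threshold
    )

    sides = {
        "drug": (drug_similarity, drug_sharing, train_affinity.drug_ids),
        "protein": (protein_similarity, prot_sharing, train_affinity.protein_ids),
    }

    # cached per-entity SAFs (no pair exclusion) used for AAF aggregation
    saf_cache: dict[str, dict[str, SAFVector]] = {}
    aaf_cache: dict[str, dict[str, np.ndarray]] = {}
    block_defs: list[tuple[str, str, str, float | None]] = []  # name parts per side
    for thr in config.sim_thresholds:
        block_defs.append((f"AAF.sim.t{thr:g}", "similarity", "threshold", thr))
    for thr in config.sharing_thresholds:
        block_defs.append((f"AAF.share.t{thr:g}", "sharing", "threshold", thr))
    if config.top5exp:
        block_defs.append(("AAF.sim.top5exp", "similarity", "top5exp", None))

    for side, (sim, share, ids) in sides.items():
        saf_cache[side] = {
            e: extract_saf(e, side, sim, train_affinity, cold_fill=cold_fill)
            for e in ids
        }
        aaf_cache[side] = {}
        for e in ids:
            parts = []
            for _, source, scheme, thr in block_defs:
                matrix = sim if source == "similarity" else share
                if scheme == "threshold":
                    nbrs = select_neighbors_threshold(matrix, e, thr)
                else:
                    nbrs = select_neighbors_top5exp(sim, e)
                parts.append(
                    aggregate_aaf(
                        nbrs,
                        saf_cache[side],
                        weights=config.aggregation,
                        similarity=matrix,
                        cold_fill=cold_fill,
                    )
                )
            aaf_cache[side][e] = np.concatenate(parts)

    # column names + provenance, fixed order: drug SAF, drug AAFs, protein
    # SAF, protein AAFs
    columns: list[str] = []
    provenance: dict[str, dict] = {}
    for side in ("drug", "protein"):
        for stat in SAF_STAT_NAMES:
            name = f"{side}.SAF.{stat}"
            columns.append(name)
            provenance[name] = _provenance(side, "SAF", "self", "self", None, stat)
        for bname, source, scheme, thr in block_defs:
            for stat in SAF_STAT_NAMES:
                name = f"{side}.{bname}.{stat}"
                columns.append(name)
                provenance[name] = _provenance(side, "AAF", source, scheme, thr, stat)

    # cached similarity-profile statistics never depend on pair exclusion
    dmap = {d: i for i, d in enumerate(affinity.drug_ids)}
    pmap = {p: i for i, p in enumerate(affinity.protein_ids)}

    def assemble(pairs: list[tuple[str, str]], is_train: bool) -> FeatureTable:
        rows = np.empty((len(pairs), len(columns)))
        for k, (d, p) in enumerate(pairs):
            if is_train:
                dsaf = extract_saf(
                    d, "drug", drug_similarity, train_affinity,
                    exclude_pair=p, cold_fill=cold_fill,
                ).values
                psaf = extract_saf(
                    p, "protein", protein_similarity, train_affinity,
                    exclude_pair=d, cold_fill=cold_fill,
                ).values
            else:
                dsaf = saf_cache["drug"][d].values
                psaf = saf_cache["protein"][p].values
            rows[k] = np.concatenate(
                [dsaf, aaf_cache["drug"][d], psaf, aaf_cache["protein"][p]]
            )
        y = np.array([affinity.values[dmap[d], pmap[p]] for d, p in pairs])
        query = np.array([split.query_of[pair] for pair in pairs], dtype=object)
        X = pd.DataFrame(rows, columns=columns)
        return FeatureTable(list(pairs), X, y, query, dict(provenance))

    train_table = assemble(split.train_pairs, is_train=True)
    test_table = assemble(split.test_pairs, is_train=False)
    logger.info(
        "feature table: %d train rows, %d test rows, %d columns",
        len(train_table.pairs), len(test_table.pairs), len(columns),
    )
    return train_table, test_table
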