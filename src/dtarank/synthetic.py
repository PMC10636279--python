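"""Synthetic drug-target affinity datasets with planted latent structure.

The generator emulates the two shapes of public DTA benchmarks — a small
dense kinase panel (hundreds of proteins x tens of drugs, every pair
measured) and a large sparse screen (most pairs unmeasured) — with a
low-rank factor model in which similar entities have similar affinity
profiles, the premise that neighbor-derived (AAF) features exploit.

Model
-----
Each drug d and protein p carries a latent factor ``u_d, v_p in R^r`` drawn
iid from a spherical (isotropic) Gaussian centered away from the origin::

    u = mu * e + N(0, s^2 I_r),   e = 1/sqrt(r) * (1, ..., 1)

and the affinity is ``base + scale * (u . v) + N(0, noise_sd^2)``.  The
nonzero center gives drugs and proteins genuine main effects (promiscuous
targets, broadly potent compounds) on top of the low-rank interaction —
the structure real affinity panels show and the reason per-entity profile
statistics are predictive at all.  Similarity matrices are the cosine
similarity of the latent factors mapped to [0, 1] via (x + 1) / 2, so
entities with aligned factors are both "similar" and correlated in their
affinity rows.  Missingness is MCAR.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .data_model import AffinityMatrix, SimilarityMatrix

__all__ = ["SyntheticConfig", "generate", "davis_like_config", "kiba_like_config"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-structure generator.

    Defaults describe the standard desk-scale study condition: 60 drugs x
    100 proteins, rank-3 latent structure, pKd-like scale (base 7.0,
    spread ~1.5 units), measurement noise 0.3 affinity units, fully
    observed.
    """

    n_drugs: int = 60
    n_proteins: int = 100
    latent_rank: int = 3
    noise_sd: float = 0.3
    missing_fraction: float = 0.0
    affinity_base: float = 7.0
    affinity_scale: float = 1.5
    latent_mean: float = 1.0
    latent_sd: float = 0.5
    seed: int = 42

    def validate(self) -> None:
        if self.n_drugs < 2 or self.n_proteins < 2:
            raise ValueError("need at least 2 drugs and 2 proteins")
        if not 1 <= self.latent_rank <= min(self.n_drugs, self.n_proteins):
            raise ValueError(
                f"latent_rank {self.latent_rank} must be in "
                f"[1, {min(self.n_drugs, self.n_proteins)}]"
            )
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.noise_sd < 0 or self.latent_sd < 0:
            raise ValueError("standard deviations must be >= 0")


def davis_like_config(**overrides) -> SyntheticConfig:
    """Dense kinase-panel shape: 68 drugs x 442 proteins, all pairs observed."""
    base = dict(n_drugs=68, n_proteins=442, missing_fraction=0.0)
    base.update(overrides)
    return SyntheticConfig(**base)


def kiba_like_config(**overrides) -> SyntheticConfig:
    """Sparse screen shape: 2111 drugs x 229 proteins, ~24% of pairs observed."""
    base = dict(n_drugs=2111, n_proteins=229, missing_fraction=0.755)
    base.update(overrides)
    return SyntheticConfig(**base)


def _cosine_similarity_matrix(factors: np.ndarray, ids: list[str]) -> SimilarityMatrix:
    norms = np.linalg.norm(factors, axis=1)
    norms[norms == 0] = 1.0
    unit = factors / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    sim = (cos + 1.0) / 2.0
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(ids, sim)


def generate(
    config: SyntheticConfig,
) -> tuple[SimilarityMatrix, SimilarityMatrix, AffinityMatrix, dict]:
    """Draw one dataset: drug similarity, protein similarity, affinity, truth.

    Fully determined by ``config`` (including its seed).  ``truth`` holds
    the latent factors and the noiseless affinity surface for recovery
    tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    r = config.latent_rank
    center = config.latent_mean * np.ones(r) / np.sqrt(r)
    u = center + config.latent_sd * rng.standard_normal((config.n_drugs, r))
    v = center + config.latent_sd * rng.standard_normal((config.n_proteins, r))

    signal = config.affinity_base + config.affinity_scale * (u @ v.T)
    noise = config.noise_sd * rng.standard_normal(signal.shape)
    values = signal + noise

    observed = rng.random(signal.shape) >= config.missing_fraction
    # keep at least one observation per drug and per protein so every entity
    # has a defined profile
    for i in range(config.n_drugs):
        if not observed[i].any():
            observed[i, rng.integers(config.n_proteins)] = True
    for j in range(config.n_proteins):
        if not observed[:, j].any():
            observed[rng.integers(config.n_drugs), j] = True

    drug_ids = [f"D{i:04d}" for i in range(config.n_drugs)]
    protein_ids = [f"P{i:04d}" for i in range(config.n_proteins)]

    drug_sim = _cosine_similarity_matrix(u, drug_ids)
    prot_sim = _cosine_similarity_matrix(v, protein_ids)
    affinity = AffinityMatrix(drug_ids, protein_ids, values, observed)
    truth = {
        "config": asdict(config),
        "drug_factors": u,
        "protein_factors": v,
        "noiseless_affinity": signal,
    }
    return drug_sim, prot_sim, affinity, truth


def write_truth(truth: dict, path: str | Path) -> None:
    """Serialize the latent truth (factors, config) as JSON."""
    payload = {
        "config": truth["config"],
        "drug_factors": truth["drug_factors"].tolist(),
        "protein_factors": truth["protein_factors"].tolist(),
    }
    Path(path).write_text(json.dumps(payload))
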