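"""Shared fixtures: hand-built oracle matrices, the standard synthetic
dataset, and planted-signal regression tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dtarank import data_model, features, rank_model, synthetic

# hyperparameters small enough for desk-scale fixtures; mid-range values of
# the boosted-tree search space otherwise
FAST_PARAMS = {"n_estimators": 200, "max_depth": 4, "learning_rate": 0.06,
               "min_data_in_leaf": 5}


@pytest.fixture(scope="session")
def saf_fixture():
    """Matrices engineered so drug 'D0' has similarity profile
    [0.2, 0.4, 0.6, 0.8] and affinity profile [5.0, 5.0, 6.3, 7.1, 7.9, 8.2]."""
    drug_ids = [f"D{i}" for i in range(5)]
    protein_ids = [f"P{i}" for i in range(6)]
    sim = np.full((5, 5), 0.5)
    np.fill_diagonal(sim, 1.0)
    sim[0, 1:] = [0.2, 0.4, 0.6, 0.8]
    sim[1:, 0] = [0.2, 0.4, 0.6, 0.8]
    drug_sim = data_model.SimilarityMatrix(drug_ids, sim)

    aff = np.full((5, 6), 6.0)
    aff[0] = [5.0, 5.0, 6.3, 7.1, 7.9, 8.2]
    affinity = data_model.AffinityMatrix(
        drug_ids, protein_ids, aff, np.ones((5, 6), dtype=bool)
    )
    return drug_sim, affinity


@pytest.fixture(scope="session")
def std_dataset():
    """The standard planted-structure study condition: 60 drugs x 100
    proteins, rank 3, noise 0.3, fully observed, seed 42."""
    config = synthetic.SyntheticConfig(seed=42)
    drug_sim, prot_sim, affinity, truth = synthetic.generate(config)
    return config, drug_sim, prot_sim, affinity, truth


@pytest.fixture(scope="session")
def std_split(std_dataset):
    _, _, _, affinity, _ = std_dataset
    return data_model.make_split(affinity, "S1", 0.2, 42)


@pytest.fixture(scope="session")
def std_tables(std_dataset, std_split):
    _, drug_sim, prot_sim, affinity, _ = std_dataset
    return features.build_feature_table(std_split, drug_sim, prot_sim, affinity)


@pytest.fixture(scope="session")
def std_model(std_tables):
    train_tbl, _ = std_tables
    return rank_model.train(train_tbl, seed=42)


@pytest.fixture(scope="session")
def permuted_pipeline_ci(std_dataset, std_split):
    """Permutation null: shuffle the training affinities *before* feature
    extraction, rerun the whole pipeline, and score the predictions
    against the true held-out labels."""
    _, drug_sim, prot_sim, affinity, _ = std_dataset
    rng = np.random.default_rng(42)
    vals = affinity.values.copy()
    idx = [(affinity.drug_index(d), affinity.protein_index(p))
           for d, p in std_split.train_pairs]
    shuffled = rng.permutation(np.array([vals[i, j] for i, j in idx]))
    for (i, j), v in zip(idx, shuffled):
        vals[i, j] = v
    perm_aff = data_model.AffinityMatrix(
        affinity.drug_ids, affinity.protein_ids, vals, affinity.observed
    )
    train_tbl, test_tbl = features.build_feature_table(
        std_split, drug_sim, prot_sim, perm_aff
    )
    model = rank_model.train(train_tbl, seed=42)
    true_y = np.array(
        [affinity.values[affinity.drug_index(d), affinity.protein_index(p)]
         for d, p in test_tbl.pairs]
    )
    from dtarank.metrics import concordance_index

    return concordance_index(true_y, model.predict_array(test_tbl.X))


def make_planted_tables(
    n_train: int = 600,
    n_test: int = 200,
    n_features: int = 200,
    n_active: int = 8,
    noise: float = 0.1,
    seed: int = 11,
) -> tuple[features.FeatureTable, features.FeatureTable]:
    """Regression tables where only the first ``n_active`` columns carry
    signal; the rest are independent noise."""
    rng = np.random.default_rng(seed)
    n = n_train + n_test
    X = rng.normal(size=(n, n_features))
    w = np.zeros(n_features)
    w[:n_active] = np.linspace(1.0, 2.0, n_active) * np.resize([1, -1], n_active)
    y = X @ w + 0.5 * X[:, 0] * X[:, 1] + noise * rng.normal(size=n)
    cols = [f"f{i:03d}" for i in range(n_features)]
    query = rng.choice([f"q{i}" for i in range(10)], size=n)

    def table(sl):
        return features.FeatureTable(
            [(f"D{i}", f"P{i}") for i in range(sl.start, sl.stop)],
            pd.DataFrame(X[sl], columns=cols),
            y[sl],
            query[sl].astype(object),
        )

    return table(slice(0, n_train)), table(slice(n_train, n))


@pytest.fixture(scope="session")
def planted_tables():
    return make_planted_tables()


@pytest.fixture(scope="session")
def planted_small_tables():
    """40-column variant used where every dimension step retrains a model."""
    return make_planted_tables(n_train=400, n_test=150, n_features=40,
                               n_active=8, seed=13)
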