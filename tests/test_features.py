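"""SAF extraction, neighbor schemes, AAF aggregation and table assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtarank import data_model, features
from dtarank.features import (
    BlockConfig,
    SAF_STAT_NAMES,
    SAFVector,
    aggregate_aaf,
    build_feature_table,
    extract_saf,
    select_neighbors_threshold,
    select_neighbors_top5exp,
)


class TestExtractSAF:
    def test_hand_computed_statistics(self, saf_fixture):
        """All 22 statistics on the engineered profile, hand-computed under
        linear-interpolation percentiles and round-to-2dp smallest-tie mode."""
        drug_sim, affinity = saf_fixture
        saf = extract_saf("D0", "drug", drug_sim, affinity).as_dict()
        expected = {
            "sim_mean": 0.5,
            "sim_p50": 0.5,
            "sim_p75": 0.65,
            "sim_p85": 0.71,
            "sim_p95": 0.77,
            "aff_mean": 39.5 / 6,
            "aff_count": 6.0,
            "aff_mode": 5.0,
            "aff_p25": 5.325,
            "aff_p50": 6.7,
            "aff_p75": 7.7,
            "aff_top1": 8.2, "aff_top2": 7.9, "aff_top3": 7.1,
            "aff_top4": 6.3, "aff_top5": 5.0,
            "aff_low1": 5.0, "aff_low2": 5.0, "aff_low3": 6.3,
            "aff_low4": 7.1, "aff_low5": 7.9,
            "aff_row_mean": 39.5 / 6,
        }
        for name, want in expected.items():
            assert saf[name] == pytest.approx(want, abs=1e-12), name

    def test_exclude_pair_masks_one_cell(self, saf_fixture):
        drug_sim, affinity = saf_fixture
        saf = extract_saf("D0", "drug", drug_sim, affinity,
                          exclude_pair="P5").as_dict()
        # profile becomes [5.0, 5.0, 6.3, 7.1, 7.9]
        assert saf["aff_count"] == 5
        assert saf["aff_top1"] == 7.9
        assert saf["aff_mean"] == pytest.approx(31.3 / 5)

    def test_cold_entity_gets_fill(self, saf_fixture):
        drug_sim, affinity = saf_fixture
        cold = data_model.AffinityMatrix(
            affinity.drug_ids, affinity.protein_ids, affinity.values,
            np.ones_like(affinity.observed) * np.array([[False]] + [[True]] * 4),
        )
        saf = extract_saf("D0", "drug", drug_sim, cold, cold_fill=6.5).as_dict()
        assert saf["aff_count"] == 0
        for name in SAF_STAT_NAMES[5:]:
            if name != "aff_count":
                assert saf[name] == 6.5

    def test_padding_repeats_last_order_statistic(self, saf_fixture):
        drug_sim, _ = saf_fixture
        aff = data_model.AffinityMatrix(
            drug_sim.entity_ids, ["P0", "P1"],
            np.tile([4.0, 9.0], (5, 1)), np.ones((5, 2), bool),
        )
        saf = extract_saf("D0", "drug", drug_sim, aff).as_dict()
        assert [saf[f"aff_top{i}"] for i in range(1, 6)] == [9, 4, 4, 4, 4]
        assert [saf[f"aff_low{i}"] for i in range(1, 6)] == [4, 9, 9, 9, 9]

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_order_invariants_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n_d, n_p = rng.integers(3, 8), rng.integers(6, 12)
        ids = [f"D{i}" for i in range(n_d)]
        sim = rng.uniform(size=(n_d, n_d))
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 1.0)
        aff = data_model.AffinityMatrix(
            ids, [f"P{j}" for j in range(n_p)],
            rng.uniform(4, 10, (n_d, n_p)), rng.random((n_d, n_p)) > 0.3,
        )
        entity = ids[int(rng.integers(n_d))]
        saf = extract_saf(entity, "drug", data_model.SimilarityMatrix(ids, sim),
                          aff).as_dict()
        assert saf["sim_p50"] <= saf["sim_p75"] <= saf["sim_p85"] <= saf["sim_p95"]
        tops = [saf[f"aff_top{i}"] for i in range(1, 6)]
        lows = [saf[f"aff_low{i}"] for i in range(1, 6)]
        assert tops == sorted(tops, reverse=True)
        assert lows == sorted(lows)
        row = aff.values[aff.drug_index(entity)][aff.observed[aff.drug_index(entity)]]
        assert saf["aff_count"] == len(row)


class TestNeighborSelection:
    def _sim(self, row):
        n = len(row)
        m = np.full((n, n), 0.1)
        m[0], m[:, 0] = row, row
        np.fill_diagonal(m, 1.0)
        return data_model.SimilarityMatrix([f"E{i}" for i in range(n)], m)

    def test_threshold_filter_and_order(self):
        sim = self._sim([1.0, 0.9, 0.5, 0.2])
        ns = select_neighbors_threshold(sim, "E0", 0.4)
        assert ns.neighbor_ids == ["E1", "E2"]

    def test_nothing_exceeds_one(self):
        sim = self._sim([1.0, 0.9, 0.5, 0.2])
        assert select_neighbors_threshold(sim, "E0", 1.0).neighbor_ids == []

    def test_tie_break_by_id(self):
        sim = self._sim([1.0, 0.5, 0.5, 0.2])
        ns = select_neighbors_threshold(sim, "E0", 0.4)
        assert ns.neighbor_ids == ["E1", "E2"]

    def test_threshold_is_strict(self):
        sim = self._sim([1.0, 0.4, 0.5, 0.2])
        assert select_neighbors_threshold(sim, "E0", 0.4).neighbor_ids == ["E2"]

    def _brute_force_top5exp(self, sim, entity):
        def top5(e):
            i = sim.index(e)
            others = [(-(sim.values[i, j]), sim.entity_ids[j])
                      for j in range(len(sim.entity_ids)) if j != i]
            return [eid for _, eid in sorted(others)][:5]

        out, seen = [], {entity}
        for nb in top5(entity):
            if nb not in seen:
                out.append(nb)
                seen.add(nb)
        for nb in top5(entity):
            for nb2 in top5(nb):
                if nb2 not in seen:
                    out.append(nb2)
                    seen.add(nb2)
        return out

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_top5exp_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        m = rng.uniform(size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        sim = data_model.SimilarityMatrix([f"E{i:02d}" for i in range(n)], m)
        ns = select_neighbors_top5exp(sim, "E03")
        assert ns.neighbor_ids == self._brute_force_top5exp(sim, "E03")
        assert "E03" not in ns.neighbor_ids
        assert len(ns.neighbor_ids) <= 30

    def test_small_matrix_warns_and_returns_all(self):
        m = np.full((4, 4), 0.5)
        np.fill_diagonal(m, 1.0)
        sim = data_model.SimilarityMatrix(list("ABCD"), m)
        with pytest.warns(UserWarning, match="top5exp"):
            ns = select_neighbors_top5exp(sim, "A")
        assert sorted(ns.neighbor_ids) == ["B", "C", "D"]

    def test_all_tied_row_gives_id_order(self):
        m = np.full((7, 7), 0.0)
        np.fill_diagonal(m, 1.0)
        sim = data_model.SimilarityMatrix([f"E{i}" for i in range(7)], m)
        ns = select_neighbors_top5exp(sim, "E3")
        assert ns.neighbor_ids[:5] == ["E0", "E1", "E2", "E4", "E5"]


class TestAggregateAAF:
    def _saf(self, eid, fill):
        return SAFVector(eid, "drug", np.full(22, float(fill)))

    def _neighbors(self, ids):
        return features.NeighborSet("X", ids, "threshold", "similarity", 0.5)

    def test_single_neighbor_is_identity(self):
        saf_of = {"A": self._saf("A", 3.0)}
        out = aggregate_aaf(self._neighbors(["A"]), saf_of)
        assert np.array_equal(out, saf_of["A"].values)

    def test_two_point_mean(self):
        saf_of = {"A": self._saf("A", 0.4), "B": self._saf("B", 0.6)}
        assert aggregate_aaf(self._neighbors(["A", "B"]), saf_of)[0] == pytest.approx(0.5)

    def test_similarity_weighted_mean(self):
        ids = ["X", "A", "B"]
        m = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]])
        sim = data_model.SimilarityMatrix(ids, m)
        saf_of = {"A": self._saf("A", 10.0), "B": self._saf("B", 20.0)}
        out = aggregate_aaf(self._neighbors(["A", "B"]), saf_of,
                            weights="similarity", similarity=sim)
        assert out[5] == pytest.approx(11.0)

    def test_empty_set_gives_cold_fill(self):
        out = aggregate_aaf(self._neighbors([]), {}, cold_fill=6.25)
        assert (out == 6.25).all()

    def test_equal_weights_equal_unweighted(self):
        ids = ["X", "A", "B"]
        m = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.3], [0.5, 0.3, 1.0]])
        sim = data_model.SimilarityMatrix(ids, m)
        rng = np.random.default_rng(5)
        saf_of = {e: SAFVector(e, "drug", rng.normal(size=22)) for e in "AB"}
        w = aggregate_aaf(self._neighbors(["A", "B"]), saf_of,
                          weights="similarity", similarity=sim)
        u = aggregate_aaf(self._neighbors(["A", "B"]), saf_of)
        assert np.allclose(w, u, atol=1e-12)


class TestBuildFeatureTable:
    def test_column_count_matches_config_arithmetic(self, std_tables):
        train_tbl, test_tbl = std_tables
        config = BlockConfig()
        # 2 sides x 22 stats x (1 SAF block + 3 sim-threshold + 2
        # sharing-threshold + 1 top5exp AAF blocks)
        assert config.n_columns() == 2 * 22 * (1 + 6) == 308
        assert len(train_tbl.feature_names) == 308
        assert train_tbl.feature_names == test_tbl.feature_names

    def test_no_missing_values_and_unique_columns(self, std_tables):
        train_tbl, test_tbl = std_tables
        for tbl in (train_tbl, test_tbl):
            assert not tbl.X.isna().any().any()
            assert not tbl.X.columns.duplicated().any()

    def test_provenance_covers_every_column(self, std_tables):
        train_tbl, _ = std_tables
        assert set(train_tbl.provenance) == set(train_tbl.feature_names)
        for name, prov in train_tbl.provenance.items():
            assert prov["block"] in ("SAF", "AAF")
            assert prov["statistic"] in SAF_STAT_NAMES

    def test_build_determinism(self, std_dataset, std_split):
        _, drug_sim, prot_sim, affinity, _ = std_dataset
        a_train, a_test = build_feature_table(std_split, drug_sim, prot_sim,
                                              affinity)
        b_train, b_test = build_feature_table(std_split, drug_sim, prot_sim,
                                              affinity)
        assert a_train.X.equals(b_train.X) and a_test.X.equals(b_test.X)
        assert np.array_equal(a_train.y, b_train.y)

    def test_empty_block_config_rejected(self, std_dataset, std_split):
        _, drug_sim, prot_sim, affinity, _ = std_dataset
        cfg = BlockConfig(sim_thresholds=(), sharing_thresholds=(),
                          top5exp=False)
        with pytest.raises(ValueError, match="AAF blocks"):
            build_feature_table(std_split, drug_sim, prot_sim, affinity, cfg)

    def test_cold_drugs_have_fill_saf_but_informative_aaf(
        self, std_dataset, std_split, std_tables
    ):
        _, _, _, affinity, _ = std_dataset
        _, test_tbl = std_tables
        train_mean = np.mean(
            [affinity.values[affinity.drug_index(d), affinity.protein_index(p)]
             for d, p in std_split.train_pairs]
        )
        assert (test_tbl.X["drug.SAF.aff_count"] == 0).all()
        assert test_tbl.X["drug.SAF.aff_mean"].to_numpy() == pytest.approx(
            np.full(len(test_tbl.pairs), train_mean)
        )
        # neighbor-derived columns must still vary across cold drugs
        assert test_tbl.X["drug.AAF.sim.top5exp.aff_mean"].nunique() > 1

    def test_table_roundtrip_and_svmlight_export(self, std_tables, tmp_path):
        _, test_tbl = std_tables
        test_tbl.to_files(tmp_path / "tbl")
        back = features.FeatureTable.from_files(tmp_path / "tbl")
        assert back.feature_names == test_tbl.feature_names
        assert np.allclose(back.X.to_numpy(), test_tbl.X.to_numpy(),
                           rtol=0, atol=1e-10)
        assert np.array_equal(back.query, test_tbl.query)

        test_tbl.to_svmlight(tmp_path / "tbl.svm")
        first = (tmp_path / "tbl.svm").read_text().splitlines()[0].split()
        assert first[1].startswith("qid:")
        assert len(first) == 2 + len(test_tbl.feature_names)


class TestLeakage:
    def test_zeroing_test_labels_changes_no_test_feature(self, std_dataset,
                                                         std_split, std_tables):
        """Feature construction must never read held-out labels."""
        _, drug_sim, prot_sim, affinity, _ = std_dataset
        _, test_tbl = std_tables
        mutated = affinity.values.copy()
        for d, p in std_split.test_pairs:
            mutated[affinity.drug_index(d), affinity.protein_index(p)] = 0.0
        aff2 = data_model.AffinityMatrix(
            affinity.drug_ids, affinity.protein_ids, mutated, affinity.observed
        )
        _, test2 = build_feature_table(std_split, drug_sim, prot_sim, aff2)
        assert test2.X.equals(test_tbl.X)

    def test_train_pair_own_label_is_excluded(self, std_dataset, std_split):
        """A train pair's profile statistics must ignore its own label: the
        drug-side affinity count equals the drug's train pairs minus one."""
        _, drug_sim, prot_sim, affinity, _ = std_dataset
        train_tbl, _ = build_feature_table(std_split, drug_sim, prot_sim,
                                           affinity)
        from collections import Counter

        per_drug = Counter(d for d, _ in std_split.train_pairs)
        counts = train_tbl.X["drug.SAF.aff_count"].to_numpy()
        expected = np.array([per_drug[d] - 1 for d, _ in train_tbl.pairs])
        assert np.array_equal(counts, expected)
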