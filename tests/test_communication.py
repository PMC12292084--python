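import itertools
import math

import numpy as np
import pandas as pd
import pytest

from scstage.communication import (
    ConditionNetwork,
    LRDatabase,
    differential_network,
    group_mean_expression,
    interaction_scores,
    network_summary,
    pathway_flow,
    permutation_pvalues,
)
from scstage.simulate import PlantedLRPair, SimConfig, generate_single_cell_dataset

from .conftest import make_norm


def toy_db(rows=None):
    rows = rows or [
        ("LR1", "L1", "R1", "pathA"),
        ("LR2", "L2", "R2", "pathB"),
    ]
    return LRDatabase.from_frame(
        pd.DataFrame(rows, columns=["name", "ligand_genes", "receptor_genes", "pathway"])
    )


class TestGroupMeans:
    def test_single_gene_plain_mean(self):
        arr = np.log1p(np.array([[2.0, 4.0, 6.0, 0.0]]))
        norm = make_norm(arr, gene_ids=["L1"])
        means = group_mean_expression(norm, ["a", "a", "b", "b"], ["L1"])
        assert means["a"] == pytest.approx(3.0)
        assert means["b"] == pytest.approx(3.0)

    def test_zero_subunit_zeroes_complex(self):
        arr = np.log1p(np.array([[2.0, 2.0], [0.0, 0.0]]))
        norm = make_norm(arr, gene_ids=["s1", "s2"])
        means = group_mean_expression(norm, ["a", "a"], ["s1", "s2"])
        assert means["a"] == 0.0

    def test_geometric_mean(self):
        arr = np.log1p(np.array([[1.0], [4.0]]))
        norm = make_norm(arr, gene_ids=["s1", "s2"])
        means = group_mean_expression(norm, ["a"], ["s1", "s2"])
        assert means["a"] == pytest.approx(2.0)


class TestInteractionScores:
    def _norm(self, ligand_by_type, receptor_by_type, n_per_type=3):
        # two types a, b; constant expression within a type
        cells, lig, rec = [], [], []
        for t in ("a", "b"):
            for _ in range(n_per_type):
                cells.append(t)
                lig.append(ligand_by_type[t])
                rec.append(receptor_by_type[t])
        arr = np.log1p(np.array([lig, rec], dtype=float))
        return make_norm(arr, gene_ids=["L1", "R1"]), cells

    def test_absent_ligand_zero_strength(self):
        norm, cells = self._norm({"a": 0.0, "b": 1.0}, {"a": 1.0, "b": 1.0})
        db = toy_db([("LR1", "L1", "R1", "p")])
        scores = interaction_scores(norm, cells, db)
        row = scores[(scores.sender == "a") & (scores.receiver == "b")]
        assert row["strength"].iloc[0] == 0.0

    def test_product_of_means(self):
        norm, cells = self._norm({"a": 2.0, "b": 0.0}, {"a": 0.0, "b": 3.0})
        db = toy_db([("LR1", "L1", "R1", "p")])
        scores = interaction_scores(norm, cells, db)
        row = scores[(scores.sender == "a") & (scores.receiver == "b")]
        assert row["strength"].iloc[0] == pytest.approx(6.0)

    def test_bilinearity_under_doubling(self):
        norm, cells = self._norm({"a": 2.0, "b": 1.0}, {"a": 1.0, "b": 3.0})
        db = toy_db([("LR1", "L1", "R1", "p")])
        s1 = interaction_scores(norm, cells, db)["strength"].to_numpy()
        doubled = make_norm(
            np.log1p(2.0 * np.expm1(norm.to_dense())), gene_ids=["L1", "R1"]
        )
        s2 = interaction_scores(doubled, cells, db)["strength"].to_numpy()
        assert np.allclose(s2, 4.0 * s1)

    def test_self_pairs_included(self):
        norm, cells = self._norm({"a": 1.0, "b": 1.0}, {"a": 1.0, "b": 1.0})
        scores = interaction_scores(norm, cells, toy_db([("LR1", "L1", "R1", "p")]))
        assert len(scores) == 4  # a->a, a->b, b->a, b->b

    def test_cell_duplication_invariance(self):
        norm, cells = self._norm({"a": 2.0, "b": 1.0}, {"a": 1.0, "b": 3.0})
        s1 = interaction_scores(norm, cells, toy_db([("LR1", "L1", "R1", "p")]))
        arr = norm.to_dense()
        dup = make_norm(np.hstack([arr, arr[:, :3]]), gene_ids=["L1", "R1"],
                        cell_ids=[f"c{i}" for i in range(9)])
        s2 = interaction_scores(dup, cells + ["a"] * 3, toy_db([("LR1", "L1", "R1", "p")]))
        assert np.allclose(s1["strength"].to_numpy(), s2["strength"].to_numpy())

    def test_fewer_than_two_types_errors(self):
        norm, _ = self._norm({"a": 1.0, "b": 1.0}, {"a": 1.0, "b": 1.0})
        with pytest.raises(ValueError, match="2 cell types"):
            interaction_scores(norm, ["a"] * 6, toy_db([("LR1", "L1", "R1", "p")]))


class TestPermutationP:
    def test_strong_observed_min_p(self):
        rng = np.random.default_rng(0)
        n = 40
        lig = np.concatenate([rng.uniform(9, 11, n), rng.uniform(0, 0.1, n)])
        rec = np.concatenate([rng.uniform(0, 0.1, n), rng.uniform(9, 11, n)])
        norm = make_norm(np.log1p(np.vstack([lig, rec])), gene_ids=["L1", "R1"])
        cells = ["a"] * n + ["b"] * n
        db = toy_db([("LR1", "L1", "R1", "p")])
        res = permutation_pvalues(norm, cells, db, n_perm=100, seed=1)
        row = res[(res.sender == "a") & (res.receiver == "b")]
        assert row["p"].iloc[0] == pytest.approx(1 / 101)

    def test_constant_expression_p_one(self):
        norm = make_norm(np.log1p(np.full((2, 8), 2.0)), gene_ids=["L1", "R1"])
        cells = ["a"] * 4 + ["b"] * 4
        res = permutation_pvalues(norm, cells, toy_db([("LR1", "L1", "R1", "p")]),
                                  n_perm=50, seed=2)
        assert (res["p"] == 1.0).all()

    def test_exhaustive_enumeration_6_cells(self):
        # 6 cells, 2 types: compare the seeded estimate with the exact
        # fraction over all 20 distinct label assignments
        vals = np.array([[5.0, 4.0, 3.0, 1.0, 0.5, 0.2],
                         [0.2, 0.5, 1.0, 3.0, 4.0, 5.0]])
        norm = make_norm(np.log1p(vals), gene_ids=["L1", "R1"])
        labels = ["a", "a", "a", "b", "b", "b"]
        db = toy_db([("LR1", "L1", "R1", "p")])
        obs = interaction_scores(norm, labels, db)
        res = permutation_pvalues(norm, labels, db, n_perm=2000, seed=3)
        for sender, receiver in itertools.product("ab", repeat=2):
            o = obs[(obs.sender == sender) & (obs.receiver == receiver)][
                "strength"
            ].iloc[0]
            ge = 0
            total = 0
            for pos in itertools.combinations(range(6), 3):
                perm = np.array(["b"] * 6, dtype=object)
                perm[list(pos)] = "a"
                s = interaction_scores(norm, perm, db)
                sp = s[(s.sender == sender) & (s.receiver == receiver)][
                    "strength"
                ].iloc[0]
                ge += sp >= o - 1e-12
                total += 1
            exact = ge / total
            got = res[(res.sender == sender) & (res.receiver == receiver)]["p"].iloc[0]
            assert got == pytest.approx((1 + 2000 * exact) / 2001, abs=0.05)

    def test_null_calibration(self):
        # exchangeable labels: fraction of p < 0.05 within 0.05 +/- 0.03
        rng = np.random.default_rng(4)
        n_genes = 112  # 56 interactions x 2 genes
        arr = rng.lognormal(0, 1, (n_genes, 90))
        ids = [f"g{i}" for i in range(n_genes)]
        norm = make_norm(np.log1p(arr), gene_ids=ids)
        labels = rng.choice(["a", "b", "c"], 90).tolist()
        rows = [
            (f"LR{i}", f"g{2*i}", f"g{2*i+1}", "p") for i in range(56)
        ]
        db = toy_db(rows)
        res = permutation_pvalues(norm, labels, db, n_perm=100, seed=5)
        assert len(res) == 56 * 9  # >= 500 triples
        frac = (res["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.03)


class TestNetworkSummary:
    def _scores(self, rows):
        return pd.DataFrame(
            rows, columns=["sender", "receiver", "interaction", "pathway", "strength", "p"]
        )

    def test_no_significant_zero_matrices(self):
        s = self._scores([("a", "b", "LR1", "p", 5.0, 0.5)])
        net = network_summary(s)
        assert (net.counts.to_numpy() == 0).all()
        assert (net.strength.to_numpy() == 0).all()

    def test_single_significant(self):
        s = self._scores([("a", "b", "LR1", "p", 6.0, 0.01)])
        net = network_summary(s)
        assert net.counts.loc["a", "b"] == 1
        assert net.strength.loc["a", "b"] == 6.0

    def test_brute_force_tally_three_types(self):
        rng = np.random.default_rng(6)
        rows = []
        for s_ in "abc":
            for r_ in "abc":
                for i in range(4):
                    rows.append((s_, r_, f"LR{i}", "p", rng.uniform(0, 5), rng.uniform(0, 1)))
        df = self._scores(rows)
        net = network_summary(df, alpha=0.3)
        for s_ in "abc":
            for r_ in "abc":
                sub = df[(df.sender == s_) & (df.receiver == r_) & (df.p < 0.3)]
                assert net.counts.loc[s_, r_] == len(sub)
                assert net.strength.loc[s_, r_] == pytest.approx(sub["strength"].sum())


class TestDifferentialNetwork:
    def _net(self, c, s, types=("a", "b")):
        idx = list(types)
        return ConditionNetwork(
            pd.DataFrame(c, index=idx, columns=idx),
            pd.DataFrame(s, index=idx, columns=idx),
        )

    def test_identical_zero(self):
        n = self._net([[1, 2], [0, 1]], [[0.5, 2.0], [0.0, 1.0]])
        dc, ds = differential_network(n, n)
        assert (dc.to_numpy() == 0).all() and (ds.to_numpy() == 0).all()

    def test_antisymmetry(self):
        a = self._net([[1, 2], [0, 1]], [[0.5, 2.0], [0.0, 1.0]])
        b = self._net([[0, 3], [1, 1]], [[0.1, 4.0], [0.2, 1.0]])
        dc1, ds1 = differential_network(a, b)
        dc2, ds2 = differential_network(b, a)
        assert (dc1.to_numpy() == -dc2.to_numpy()).all()
        assert np.allclose(ds1.to_numpy(), -ds2.to_numpy())

    def test_type_mismatch_errors(self):
        a = self._net([[0, 0], [0, 0]], [[0, 0], [0, 0]], types=("a", "b"))
        b = self._net([[0, 0], [0, 0]], [[0, 0], [0, 0]], types=("a", "c"))
        with pytest.raises(ValueError, match="differ"):
            differential_network(a, b)


class TestPathwayFlow:
    def _scores(self, rows):
        return pd.DataFrame(
            rows, columns=["sender", "receiver", "interaction", "pathway", "strength", "p"]
        )

    def test_neither_significant_none(self):
        early = self._scores([("a", "b", "LR1", "pathA", 3.0, 0.5)])
        late = self._scores([("a", "b", "LR1", "pathA", 3.0, 0.5)])
        flow = pathway_flow(early, late, toy_db([("LR1", "L1", "R1", "pathA")]))
        assert flow.iloc[0]["exclusive"] == "none"
        assert flow.iloc[0]["flow_early"] == 0.0

    def test_late_only_exclusive(self):
        early = self._scores([("a", "b", "LR1", "pathA", 3.0, 0.5)])
        late = self._scores([("a", "b", "LR1", "pathA", 9.0, 0.01)])
        flow = pathway_flow(early, late, toy_db([("LR1", "L1", "R1", "pathA")]))
        assert flow.iloc[0]["exclusive"] == "late"
        assert flow.iloc[0]["flow_late"] == 9.0

    def test_hand_summed_two_pathways(self):
        db = toy_db(
            [
                ("LR1", "L1", "R1", "pathA"),
                ("LR2", "L2", "R2", "pathA"),
                ("LR3", "L3", "R3", "pathB"),
            ]
        )
        early = self._scores(
            [
                ("a", "b", "LR1", "pathA", 2.0, 0.01),
                ("b", "a", "LR2", "pathA", 3.0, 0.04),
                ("a", "b", "LR3", "pathB", 7.0, 0.2),
            ]
        )
        late = self._scores(
            [
                ("a", "b", "LR1", "pathA", 1.0, 0.5),
                ("b", "a", "LR2", "pathA", 0.5, 0.01),
                ("a", "b", "LR3", "pathB", 4.0, 0.01),
            ]
        )
        flow = pathway_flow(early, late, db).set_index("pathway")
        assert flow.loc["pathA", "flow_early"] == pytest.approx(5.0)
        assert flow.loc["pathA", "flow_late"] == pytest.approx(0.5)
        assert flow.loc["pathB", "exclusive"] == "late"


class TestPlantedConditionSpecificity:
    def _planted_flow(self, seed):
        cfg = SimConfig(
            n_genes=40,
            chromosomes=(("chr1", 40),),
            n_cells_per_group={
                ("epithelial", "IA"): 60,
                ("fibroblast", "IA"): 60,
                ("epithelial", "IV"): 60,
                ("fibroblast", "IV"): 60,
            },
            lr_pairs_true=(
                PlantedLRPair(
                    "G00010", "G00011", "planted", "epithelial", "fibroblast",
                    amp_early=0.0, amp_late=25.0, receptor_bias=1.0,
                ),
            ),
            baseline_nb=(0.0, 0.2, 2.0),
            seed=seed,
        )
        ds = generate_single_cell_dataset(cfg)
        from scstage.qc import log_normalize

        norm = log_normalize(ds.counts)
        meta = ds.cell_metadata
        db = toy_db([("LRp", "G00010", "G00011", "planted"),
                     ("LRnull", "G00020", "G00021", "nullpath")])
        scores = {}
        for cond, stages in (("early", {"IA"}), ("late", {"IV"})):
            mask = meta["stage"].isin(stages).to_numpy()
            sub = norm.subset_cells(np.where(mask)[0])
            labels = meta.loc[mask, "cell_type"].tolist()
            scores[cond] = permutation_pvalues(sub, labels, db, n_perm=100, seed=seed)
        # interaction-level alpha 0.01 for exclusivity calls (late-stage
        # LR contributions are screened at the stricter cut)
        return pathway_flow(scores["early"], scores["late"], db, alpha=0.01).set_index("pathway")

    def test_late_only_pathway_called_exclusive_late(self):
        hits = 0
        seeds = range(20)
        for seed in seeds:
            flow = self._planted_flow(seed)
            hits += flow.loc["planted", "exclusive"] == "late"
        assert hits / len(seeds) >= 0.9

    def test_differential_positive_at_planted_pair(self):
        flow_seed = 1
        cfg_flow = self._planted_flow(flow_seed)
        assert cfg_flow.loc["planted", "flow_late"] > cfg_flow.loc["planted", "flow_early"]
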