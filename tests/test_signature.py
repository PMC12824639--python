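"""Differential expression, FDR, gene-module clustering and forest pruning."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tmescope import (
    ExpressionMatrix,
    GeneModuleSet,
    bh_adjust,
    cluster_genes,
    consistent_genes,
    differential_genes,
    reduce_by_forest,
    signature_pool,
)

from conftest import make_expr


def brute_force_bh(p):
    """Independent step-up oracle: q_i = min over j >= rank(i) of p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank, m + 1)
        ]
        q_sorted[rank - 1] = min(1.0, min(candidates))
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=100)
        assert (bh_adjust(p) >= p - 1e-15).all()


def _grouped_matrix(rng, n_genes=100, n_per=10, n_groups=2, shift_gene=None, shift=0.0):
    vals = rng.normal(5.0, 0.5, size=(n_genes, n_per * n_groups))
    labels = np.repeat([f"G{g}" for g in range(n_groups)], n_per)
    if shift_gene is not None:
        vals[shift_gene, labels == "G0"] += shift
    m = make_expr(vals, scale="log2")
    return m, pd.Series(labels, index=m.sample_ids)


class TestDifferentialGenes:
    def test_null_gene_flat(self, rng):
        m, labels = _grouped_matrix(rng)
        vals = m.values.copy()
        vals.iloc[0] = 7.0 + np.tile([0.0, 0.01, -0.01, 0.02, -0.02], 4)
        # identical distribution across groups: tiny effect, large p
        deg = differential_genes(ExpressionMatrix(vals, "log2"), labels, "pairwise")
        row = deg[deg["gene_id"] == "g0"].iloc[0]
        assert abs(row["effect"]) < 0.05
        assert row["p"] > 0.5

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(7)
        m, labels = _grouped_matrix(
            rng, n_genes=500, n_per=30, shift_gene=123, shift=2.0
        )
        deg = differential_genes(m, labels, contrast="pairwise")
        best = deg.sort_values("q").iloc[0]
        assert best["gene_id"] == "g123"
        assert best["q"] < 0.05

    def test_small_group_rejected(self, rng):
        m, labels = _grouped_matrix(rng, n_per=5)
        labels.iloc[:8] = "G9"  # leaves G0 with 2 samples
        with pytest.raises(ValueError, match="< 3 samples"):
            differential_genes(m, labels)

    def test_sample_order_and_label_encoding_invariance(self, rng):
        m, labels = _grouped_matrix(rng, n_genes=50, n_per=8)
        perm = rng.permutation(m.n_samples)
        m2 = ExpressionMatrix(m.values.iloc[:, perm], "log2")
        labels2 = labels.iloc[perm].map({"G0": "alpha", "G1": "beta"})
        a = differential_genes(m, labels, "pairwise").set_index("gene_id")
        b = differential_genes(m2, labels2, "pairwise").set_index("gene_id")
        np.testing.assert_allclose(
            np.abs(a["statistic"]), np.abs(b["statistic"]), atol=1e-9
        )
        np.testing.assert_allclose(a["q"], b["q"], atol=1e-9)


class TestConsistentGenes:
    @staticmethod
    def _table(contrast, sig_genes, all_genes=("A", "B", "C", "D", "E")):
        return pd.DataFrame(
            {
                "gene_id": all_genes,
                "contrast": contrast,
                "q": [0.01 if g in sig_genes else 0.5 for g in all_genes],
            }
        )

    def test_intersection(self):
        deg = pd.concat(
            [self._table("c1", {"A", "B", "C"}), self._table("c2", {"B", "C", "D"})]
        )
        assert consistent_genes(deg) == ["B", "C"]

    def test_empty_contrast_absorbs(self):
        deg = pd.concat([self._table("c1", {"A", "B"}), self._table("c2", set())])
        assert consistent_genes(deg) == []

    def test_identical_tables_idempotent(self):
        deg = pd.concat(
            [self._table("c1", {"A", "D"}), self._table("c2", {"A", "D"})]
        )
        assert consistent_genes(deg) == ["A", "D"]

    def test_single_contrast_rejected(self):
        with pytest.raises(ValueError):
            consistent_genes(self._table("c1", {"A"}))

    def test_union_pool(self):
        deg = pd.concat(
            [self._table("c1", {"A", "B"}), self._table("c2", {"B", "D"})]
        )
        assert signature_pool(deg) == ["A", "B", "D"]


class TestClusterGenes:
    def test_anticorrelated_blocks_separate(self, rng):
        t = np.linspace(-1, 1, 20)
        up = np.vstack([t + rng.normal(0, 0.05, 20) for _ in range(10)])
        down = np.vstack([-t + rng.normal(0, 0.05, 20) for _ in range(10)])
        m = make_expr(np.vstack([up, down]), scale="log2")
        mods = cluster_genes(m, k=2, seed=0)
        truth = np.repeat([0, 1], 10)
        got = np.array(
            [0 if f"g{i}" in mods.modules["GeneModule1"] else 1 for i in range(20)]
        )
        assert adjusted_rand_score(truth, got) == 1.0

    def test_duplicated_rows_same_module(self, rng):
        vals = rng.normal(size=(6, 15))
        vals[3] = vals[0]
        m = make_expr(vals, scale="log2")
        mods = cluster_genes(m, k=2, seed=1)
        for genes in mods.modules.values():
            assert ("g0" in genes) == ("g3" in genes)

    def test_planted_modules_recovered(self, small_cohort):
        truth = small_cohort["truth"]
        expr = small_cohort["expr"].to_log2()
        genes = [g for mod in truth.true_module_genes.values() for g in mod]
        from tmescope import zscore_genes

        z = zscore_genes(ExpressionMatrix(expr.values.loc[genes], "log2"))
        mods = cluster_genes(z, k=2, seed=0)
        wanted = np.array(
            [0 if g in set(truth.true_module_genes["MOD1"]) else 1 for g in z.gene_ids]
        )
        got = np.array(
            [0 if g in set(mods.modules["GeneModule1"]) else 1 for g in z.gene_ids]
        )
        assert adjusted_rand_score(wanted, got) >= 0.9

    def test_too_many_clusters_rejected(self, rng):
        m = make_expr(rng.normal(size=(3, 8)), scale="log2")
        with pytest.raises(ValueError):
            cluster_genes(m, k=5)


class TestReduceByForest:
    @staticmethod
    def _informative_setup(seed, n_noise=10):
        rng = np.random.default_rng(seed)
        n = 60
        labels = np.repeat(["A", "B"], n // 2)
        informative = np.vstack(
            [
                np.where(labels == "A", 1.0, -1.0) + rng.normal(0, 0.5, n)
                for _ in range(10)
            ]
        )
        noise = rng.normal(size=(n_noise, n))
        m = make_expr(np.vstack([informative, noise]), scale="log2")
        mods = GeneModuleSet(
            modules={
                "info": [f"g{i}" for i in range(10)],
                "noise": [f"g{i}" for i in range(10, 10 + n_noise)],
            }
        )
        return m, mods, pd.Series(labels, index=m.sample_ids)

    def test_noise_ranks_below_informative(self):
        wins = 0
        for seed in range(20):
            m, mods, labels = self._informative_setup(seed)
            _pruned, imp = reduce_by_forest(
                m, mods, labels, n_trees=100, keep_fraction=1.0, seed=seed
            )
            if imp[mods.modules["info"]].min() > imp[mods.modules["noise"]].max():
                wins += 1
        assert wins >= 19

    def test_keep_all_is_identity(self):
        m, mods, labels = self._informative_setup(1)
        pruned, _ = reduce_by_forest(m, mods, labels, n_trees=50, keep_fraction=1.0)
        for mid in mods.modules:
            assert set(pruned.modules[mid]) == set(mods.modules[mid])

    def test_half_of_ten_keeps_five(self):
        m, mods, labels = self._informative_setup(2)
        pruned, _ = reduce_by_forest(m, mods, labels, n_trees=50, keep_fraction=0.5)
        assert len(pruned.modules["info"]) == 5
        assert len(pruned.modules["noise"]) == 5

    def test_pruning_monotone_nested(self):
        m, mods, labels = self._informative_setup(3)
        kept = {}
        for frac in (0.3, 0.6, 1.0):
            pruned, _ = reduce_by_forest(
                m, mods, labels, n_trees=50, keep_fraction=frac, seed=0
            )
            kept[frac] = {mid: set(g) for mid, g in pruned.modules.items()}
        for mid in mods.modules:
            assert kept[0.3][mid] <= kept[0.6][mid] <= kept[1.0][mid]

    def test_single_class_rejected(self):
        m, mods, labels = self._informative_setup(4)
        with pytest.raises(ValueError):
            reduce_by_forest(m, mods, pd.Series("A", index=m.sample_ids))
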