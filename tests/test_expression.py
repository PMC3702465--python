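"""Expression preprocessing, clustering and overlap-score tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from netprio import (
    GeneSet,
    build_network,
    cluster_genes,
    cluster_overlap_pvalue,
    expression_rank_score,
    filter_datasets,
    preprocess,
    score_cluster_overlaps,
)
from netprio.expression import ExpressionDataset


def net_of(*genes):
    return build_network([[(a, b) for a, b in zip(genes, genes[1:])]])


class TestPreprocess:
    def test_duplicate_resolved_to_largest_mean(self):
        net = net_of("g", "h")
        raw = pd.DataFrame(
            [[1, 2, 3], [4, 5, 6], [0, 0, 0]],
            index=["g", "g", "h"], columns=["s1", "s2", "s3"],
        )
        ds = preprocess(raw, net)
        assert ds.matrix.loc["g"].tolist() == [4, 5, 6]

    def test_equal_means_keep_first_occurrence(self):
        net = net_of("g", "h")
        raw = pd.DataFrame(
            [[1, 3], [3, 1], [0, 0]], index=["g", "g", "h"], columns=["s1", "s2"]
        )
        ds = preprocess(raw, net)
        assert ds.matrix.loc["g"].tolist() == [1, 3]

    def test_null_rows_and_offnetwork_genes_dropped(self):
        net = net_of("a", "b", "c")
        raw = pd.DataFrame(
            {
                "s1": [1.0, np.nan, 2.0, 5.0],
                "s2": [1.0, 1.0, 2.0, 5.0],
            },
            index=["a", "b", "c", "zzz"],
        )
        ds = preprocess(raw, net)
        assert set(ds.matrix.index) == {"a", "c"}

    def test_too_small_raises(self):
        net = net_of("a", "b")
        raw = pd.DataFrame({"s1": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="too small"):
            preprocess(raw, net)


class TestFilterDatasets:
    def _ds(self, n_samples):
        m = pd.DataFrame(np.zeros((3, n_samples)))
        return ExpressionDataset(f"d{n_samples}", m)

    def test_strict_fewer_than_rule(self):
        kept = filter_datasets([self._ds(3), self._ds(4), self._ds(5), self._ds(7)])
        assert [d.n_samples for d in kept] == [5, 7]

    def test_min_one_is_identity(self):
        ds = [self._ds(2), self._ds(3)]
        assert filter_datasets(ds, min_samples=1) == ds

    def test_all_removed_raises(self):
        with pytest.raises(ValueError):
            filter_datasets([self._ds(2)])


class TestClusterGenes:
    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(0)
        f1, f2 = rng.normal(size=12), rng.normal(size=12)
        rows, names = [], []
        for i in range(10):
            rows.append(f1 + 0.2 * rng.normal(size=12))
            names.append(f"a{i}")
        for i in range(10):
            rows.append(f2 + 0.2 * rng.normal(size=12))
            names.append(f"b{i}")
        ds = ExpressionDataset("blocks", pd.DataFrame(rows, index=names))
        asg = cluster_genes(ds, seed=0)
        assert asg.n_clusters == 2
        block_a = asg.labels[[f"a{i}" for i in range(10)]]
        block_b = asg.labels[[f"b{i}" for i in range(10)]]
        assert block_a.nunique() == 1 and block_b.nunique() == 1
        assert block_a.iloc[0] != block_b.iloc[0]

    def test_constant_row_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(4, 8)), index=list("abcd"))
        m.loc["a"] = 1.0
        ds = ExpressionDataset("const", m)
        with pytest.warns(UserWarning, match="constant"):
            asg = cluster_genes(ds, seed=0)
        assert "a" not in asg.labels.index

    def test_labels_partition_genes(self, small_data):
        ds = small_data.datasets[0]
        asg = cluster_genes(ds, seed=3)
        assert asg.labels.notna().all()
        assert set(asg.labels.index) <= set(ds.genes)
        assert sum(len(asg.members(c)) for c in asg.table.index) == len(asg.labels)


class TestClusterOverlapPvalue:
    def test_agrees_with_exact_hypergeometric(self):
        # universe 100, goset 50, cluster of 10 fully inside the goset
        universe = [f"g{i}" for i in range(100)]
        goset = GeneSet("go", universe[:50])
        cluster = universe[:10]
        obs, mean, sd, p = cluster_overlap_pvalue(
            cluster, goset, universe, n_perm=2000, rng=1
        )
        assert obs == 10
        exact = hypergeom.sf(9, 100, 50, 10)
        assert abs(p - exact) < max(0.02, 3 * np.sqrt(exact * (1 - exact) / 2000))

    def test_goset_equals_universe_degenerate(self):
        universe = [f"g{i}" for i in range(20)]
        goset = GeneSet("go", universe)
        obs, mean, sd, p = cluster_overlap_pvalue(universe[:5], goset, universe, rng=0)
        assert sd == 0.0 and p == 1.0

    def test_disjoint_cluster_upper_tail_near_one(self):
        universe = [f"g{i}" for i in range(100)]
        goset = GeneSet("go", universe[:80])
        obs, mean, sd, p = cluster_overlap_pvalue(
            universe[90:], goset, universe, n_perm=1000, rng=2
        )
        assert obs == 0 and p > 0.99

    def test_cluster_larger_than_universe_raises(self):
        with pytest.raises(ValueError):
            cluster_overlap_pvalue(["a", "b"], GeneSet("g", ["a"]), ["a"])

    def test_empirical_method_option(self):
        universe = [f"g{i}" for i in range(50)]
        goset = GeneSet("go", universe[:25])
        *_, p = cluster_overlap_pvalue(
            universe[:8], goset, universe, n_perm=2000, rng=3, method="empirical"
        )
        exact = hypergeom.sf(7, 50, 25, 8)
        assert abs(p - exact) < max(0.02, 3 * np.sqrt(exact * (1 - exact) / 2000))


class TestExpressionRankScore:
    def _assignment(self, ds_id, clusters, pvals):
        labels = pd.Series(
            {g: lbl for lbl, genes in clusters.items() for g in genes}, name="cluster"
        )
        from scipy.stats import rankdata
        table = pd.DataFrame(
            {
                "size": [len(clusters[c]) for c in sorted(clusters)],
                "overlap": 0, "perm_mean": 0.0, "perm_sd": 1.0,
                "p": [pvals[c] for c in sorted(clusters)],
            },
            index=pd.Index(sorted(clusters), name="cluster"),
        )
        table["rank"] = rankdata(table["p"])
        from netprio import ClusterAssignment
        return ClusterAssignment(ds_id, labels, [], table)

    def test_two_cluster_extremes(self):
        asg = self._assignment("d1", {0: ["a", "b"], 1: ["c"]}, {0: 0.01, 1: 0.5})
        s_e = expression_rank_score([asg], ["a", "b", "c"])
        assert s_e["a"] == s_e["b"] == 0.0 and s_e["c"] == 1.0

    def test_gene_in_two_datasets_averages(self):
        a1 = self._assignment("d1", {0: ["g"], 1: ["h"]}, {0: 0.01, 1: 0.5})
        a2 = self._assignment("d2", {0: ["x"], 1: ["g"]}, {0: 0.01, 1: 0.5})
        s_e = expression_rank_score([a1, a2], ["g", "h", "x"])
        assert s_e["g"] == 0.5  # scaled ranks 0 and 1

    def test_absent_gene_gets_neutral(self):
        asg = self._assignment("d1", {0: ["a"], 1: ["b"]}, {0: 0.01, 1: 0.5})
        s_e = expression_rank_score([asg], ["a", "b", "zzz"])
        assert s_e["zzz"] == 0.5

    def test_single_cluster_dataset_maps_to_half(self):
        asg = self._assignment("d1", {0: ["a", "b"]}, {0: 0.2})
        s_e = expression_rank_score([asg], ["a", "b"])
        assert (s_e == 0.5).all()

    def test_cluster_rank_sum_preserved(self, small_data):
        asg = cluster_genes(small_data.datasets[0], seed=5)
        scored = score_cluster_overlaps(asg, small_data.goset, n_perm=200, seed=5)
        n = len(scored.table)
        assert scored.table["rank"].sum() == pytest.approx(n * (n + 1) / 2)
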