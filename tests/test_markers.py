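import math

import numpy as np
import pytest
from scipy.stats import norm, rankdata

from sctrim import ClusterAssignment, find_all_markers, marker_sets, rank_sum_p
from tests.conftest import make_matrix


def textbook_rank_sum_p(x, y):
    """Independent tie-corrected normal-approximation rank-sum p-value."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = rankdata(np.concatenate([x, y]))
    w = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(counts ** 3 - counts)
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    z = (w - mu) / math.sqrt(var)
    return 2 * norm.sf(abs(z))


def two_group_matrix(values_a, values_b, gene_rows):
    """gene_rows x (A cells + B cells) normalized matrix."""
    X = np.hstack([values_a, values_b])
    m = make_matrix(X)
    labels = ["A"] * values_a.shape[1] + ["B"] * values_b.shape[1]
    return m, ClusterAssignment.from_arrays(m.cell_ids, labels)


class TestRankSum:
    def test_complete_separation_exact_p(self):
        """10 vs 10 with full separation: p = 2 / C(20, 10)."""
        x, y = np.full(10, 5.0), np.zeros(10)
        assert rank_sum_p(x, y) == pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    def test_exact_path_matches_brute_enumeration_small_groups(self):
        from itertools import combinations
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=4), rng.normal(size=5)
        pooled = np.concatenate([x, y])
        ranks = rankdata(pooled)
        mu = ranks.sum() * 4 / 9
        w_obs = ranks[:4].sum()
        hits = sum(abs(ranks[list(c)].sum() - mu) >= abs(w_obs - mu) - 1e-9
                   for c in combinations(range(9), 4))
        assert rank_sum_p(x, y) == pytest.approx(hits / math.comb(9, 4), abs=1e-12)

    def test_asymptotic_path_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            x = rng.integers(0, 6, size=15).astype(float)  # plenty of ties
            y = rng.integers(0, 6, size=22).astype(float)
            assert rank_sum_p(x, y) == pytest.approx(textbook_rank_sum_p(x, y),
                                                     abs=1e-10)

    def test_all_tied_values_are_uninformative(self):
        assert rank_sum_p(np.ones(15), np.ones(20)) == 1.0


class TestFindAllMarkers:
    def test_constant_gene_never_a_marker(self):
        rng = np.random.default_rng(0)
        X = rng.exponential(size=(5, 24))
        X[2] = 1.3  # constant across all cells: log2fc = 0
        m = make_matrix(X)
        cl = ClusterAssignment.from_arrays(m.cell_ids, ["A"] * 12 + ["B"] * 12)
        table = find_all_markers(m, cl, p_adj_max=1.0, only_positive=False)
        assert "g2" not in set(table["gene"])

    def test_fully_separating_gene_statistics(self):
        a = np.zeros((1, 10)) + 5.0
        b = np.zeros((1, 10))
        m, cl = two_group_matrix(a, b, 1)
        table = find_all_markers(m, cl, p_adj_max=1.0, only_positive=False)
        row = table[(table.cluster == "A") & (table.gene == "g0")].iloc[0]
        assert row.pct_in == 1.0 and row.pct_out == 0.0
        assert row.p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)
        assert row.log2fc > 0

    def test_pvalues_match_independent_implementation(self):
        """Asymptotic p-values on a 20-gene 3-cluster fixture agree with a
        textbook rank-sum implementation to 1e-10."""
        rng = np.random.default_rng(3)
        X = rng.poisson(3.0, size=(20, 36)).astype(float)
        m = make_matrix(np.log1p(X))
        cl = ClusterAssignment.from_arrays(m.cell_ids, ["A"] * 12 + ["B"] * 12 + ["C"] * 12)
        table = find_all_markers(m, cl, min_pct=0.0, log2fc_min=0.0,
                                 p_adj_max=1.0, only_positive=False)
        by_cluster = cl.indices_by_cluster(m.cell_ids)
        dense = m.to_dense()
        for _, row in table.iterrows():
            gi = int(row.gene[1:])
            mask = np.zeros(36, dtype=bool)
            mask[by_cluster[row.cluster]] = True
            expected = textbook_rank_sum_p(dense[gi, mask], dense[gi, ~mask])
            assert row.p == pytest.approx(expected, abs=1e-10)

    def test_bonferroni_over_genes_tested_per_cluster(self):
        rng = np.random.default_rng(9)
        X = np.log1p(rng.poisson(2.0, size=(15, 30)).astype(float))
        X[0, :15] += 3.0
        X[1, 15:] += 3.0
        m = make_matrix(X)
        cl = ClusterAssignment.from_arrays(m.cell_ids, ["A"] * 15 + ["B"] * 15)
        table = find_all_markers(m, cl, min_pct=0.0, log2fc_min=0.0,
                                 p_adj_max=1.0, only_positive=False)
        for clname, sub in table.groupby("cluster"):
            g = len(sub)
            for _, row in sub.iterrows():
                assert row.p_adj == pytest.approx(min(1.0, row.p * g))

    def test_cell_order_permutation_invariance(self):
        rng = np.random.default_rng(4)
        X = np.log1p(rng.poisson(3.0, size=(10, 26)).astype(float))
        labels = ["A"] * 13 + ["B"] * 13
        m = make_matrix(X)
        cl = ClusterAssignment.from_arrays(m.cell_ids, labels)
        t1 = find_all_markers(m, cl, p_adj_max=1.0, only_positive=False)
        perm = rng.permutation(26)
        m2 = make_matrix(X[:, perm])
        cl2 = ClusterAssignment.from_arrays(m2.cell_ids, [labels[i] for i in perm])
        t2 = find_all_markers(m2, cl2, p_adj_max=1.0, only_positive=False)
        key = ["cluster", "gene"]
        merged = t1.merge(t2, on=key, suffixes=("_1", "_2"))
        assert len(merged) == len(t1) == len(t2)
        np.testing.assert_allclose(merged["p_1"], merged["p_2"], atol=1e-12)
        np.testing.assert_allclose(merged["log2fc_1"], merged["log2fc_2"],
                                   atol=1e-12)

    def test_only_positive_is_a_subset(self):
        rng = np.random.default_rng(8)
        X = np.log1p(rng.poisson(2.0, size=(12, 30)).astype(float))
        X[3, :15] *= 0.2  # depleted in A: negative marker
        m = make_matrix(X)
        cl = ClusterAssignment.from_arrays(m.cell_ids, ["A"] * 15 + ["B"] * 15)
        pos = find_all_markers(m, cl, p_adj_max=1.0, only_positive=True)
        both = find_all_markers(m, cl, p_adj_max=1.0, only_positive=False)
        pos_keys = set(zip(pos.cluster, pos.gene))
        both_keys = set(zip(both.cluster, both.gene))
        assert pos_keys <= both_keys
        assert (pos.log2fc > 0).all()

    def test_single_cluster_is_an_error(self):
        m = make_matrix(np.ones((3, 5)))
        cl = ClusterAssignment.from_arrays(m.cell_ids, ["A"] * 5)
        with pytest.raises(ValueError, match="2 clusters"):
            find_all_markers(m, cl)

    def test_marker_sets_helper(self):
        import pandas as pd
        table = pd.DataFrame({"cluster": ["A", "A", "B"],
                              "gene": ["g1", "g2", "g1"]})
        assert marker_sets(table) == {"A": {"g1", "g2"}, "B": {"g1"}}
        assert marker_sets(table.iloc[:0]) == {}
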