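import numpy as np
import pytest
from scipy.spatial.distance import cdist

from sctrim import (ClusterAssignment, compute_min_knn_distance, trim_cells,
                    trim_dist)
from sctrim.knn_trim import DEFAULT_K, quantile_type7
from tests.conftest import make_matrix, make_nd


def one_cluster(values):
    """Features x cells matrix with all cells in a single cluster."""
    m = make_matrix(values)
    return m, ClusterAssignment.from_arrays(m.cell_ids, ["A"] * m.n_cells)


class TestMinKnnDistance:
    def test_coincident_pair_has_zero_distance(self):
        m, cl = one_cluster([[1.0, 1.0], [2.0, 2.0]])
        nd = compute_min_knn_distance(m, cl, k=1)
        np.testing.assert_array_equal(nd.min_dist, [0.0, 0.0])

    def test_line_positions_match_pairwise_oracle(self):
        # cells at 0, 1, 3, 7 on a single feature; nearest gaps 1,1,2,4
        m, cl = one_cluster([[0.0, 1.0, 3.0, 7.0]])
        nd = compute_min_knn_distance(m, cl, k=2)
        np.testing.assert_array_equal(nd.min_dist, [1.0, 1.0, 2.0, 4.0])
        # second-nearest from the sorted distance lists
        np.testing.assert_array_equal([d[1] for d in nd.distances],
                                      [3.0, 2.0, 3.0, 6.0])

    def test_default_neighbourhood_is_30(self):
        assert DEFAULT_K == 30
        import inspect
        sig = inspect.signature(compute_min_knn_distance)
        assert sig.parameters["k"].default == 30

    def test_brute_force_oracle_equivalence_many_instances(self):
        """min_dist equals the row-minimum of the full pairwise matrix."""
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = rng.integers(5, 61)
            d = rng.integers(2, 51)
            X = rng.normal(size=(d, n))
            m, cl = one_cluster(X)
            k = int(rng.integers(1, n))
            nd = compute_min_knn_distance(m, cl, k=k)
            dm = cdist(X.T, X.T)
            np.fill_diagonal(dm, np.inf)
            np.testing.assert_array_equal(nd.min_dist, dm.min(axis=1))

    def test_neighbours_stay_within_cluster_and_exclude_self(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(size=(5, 20)))
        cl = ClusterAssignment.from_arrays(m.cell_ids, ["A"] * 10 + ["B"] * 10)
        nd = compute_min_knn_distance(m, cl, k=4)
        for cid, nbrs in zip(nd.cell_ids, nd.neighbor_ids):
            assert cid not in nbrs
            assert all(cl.label_of(n) == cl.label_of(cid) for n in nbrs)
            assert len(nbrs) == 4

    def test_small_cluster_uses_effective_k(self):
        m, cl = one_cluster([[0.0, 1.0, 3.0]])
        nd = compute_min_knn_distance(m, cl, k=30)  # c-1 = 2 neighbours
        assert all(len(d) == 2 for d in nd.distances)

    def test_singleton_cluster_warns_with_infinite_sentinel(self):
        m = make_matrix([[0.0, 1.0, 2.0]])
        cl = ClusterAssignment.from_arrays(m.cell_ids, ["A", "A", "B"])
        with pytest.warns(UserWarning, match="singleton"):
            nd = compute_min_knn_distance(m, cl, k=1)
        assert nd.min_dist[2] == np.inf

    def test_rejects_counts_layer_and_bad_k(self):
        m, cl = one_cluster([[0.0, 1.0]])
        with pytest.raises(ValueError):
            compute_min_knn_distance(m, cl, k=0)
        counts = make_matrix([[1, 2]], layer="counts")
        with pytest.raises(ValueError, match="normalized"):
            compute_min_knn_distance(counts, cl.subset(counts.cell_ids), k=1)

    def test_unlabelled_cell_is_an_error(self):
        m = make_matrix([[0.0, 1.0]])
        cl = ClusterAssignment({"c0": "A"})
        with pytest.raises(KeyError, match="c1"):
            compute_min_knn_distance(m, cl, k=1)


class TestTrimCells:
    def test_alpha_zero_flags_nothing(self):
        nd, cl = make_nd({"A": np.arange(1, 11), "B": [0.5, 0.7, 0.9]})
        res = trim_cells(nd, cl, alpha=0.0)
        assert res.extreme_ids == []

    def test_enumeration_oracle_values_one_to_ten(self):
        """alpha=0.2 on min_dist 1..10: type-7 threshold 8.2, flags {9, 10}."""
        nd, cl = make_nd({"A": np.arange(1, 11)})
        res = trim_cells(nd, cl, alpha=0.2)
        assert res.thresholds["A"] == pytest.approx(8.2)
        assert sorted(res.min_dist[res.flags == "extreme"]) == [9.0, 10.0]

    def test_ten_percent_rule_flags_ten_largest_of_hundred(self):
        rng = np.random.default_rng(4)
        vals = rng.permutation(np.linspace(0.1, 30.0, 100))  # distinct
        nd, cl = make_nd({"A": vals})
        res = trim_cells(nd, cl, alpha=0.10)
        flagged = set(res.min_dist[res.flags == "extreme"])
        assert flagged == set(np.sort(vals)[-10:])

    def test_nestedness_of_flagged_sets_in_alpha(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            sizes = rng.integers(3, 40, size=rng.integers(1, 4))
            nd, cl = make_nd({f"c{i}": rng.exponential(size=s)
                              for i, s in enumerate(sizes)})
            sets = [set(trim_cells(nd, cl, alpha=a).extreme_ids)
                    for a in (0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4)]
            for s_small, s_big in zip(sets, sets[1:]):
                assert s_small <= s_big

    def test_ties_at_threshold_stay_core(self):
        nd, cl = make_nd({"A": [1.0, 1.0, 1.0, 1.0]})
        res = trim_cells(nd, cl, alpha=0.25)
        assert res.extreme_ids == []

    def test_singletons_never_trimmed(self):
        nd, cl = make_nd({"A": [np.inf], "B": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="singleton"):
            res = trim_cells(nd, cl, alpha=0.3)
        assert res.flags["A_0"] == "core"

    def test_alpha_domain(self):
        nd, cl = make_nd({"A": [1.0, 2.0]})
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                trim_cells(nd, cl, alpha=bad)


class TestTrimDist:
    def test_keep_frac_one_is_identity(self):
        rng = np.random.default_rng(0)
        m, cl = one_cluster(rng.normal(size=(4, 15)))
        res, trimmed = trim_dist(m, cl, knn_k=3, keep_frac=1.0)
        assert trimmed.cell_ids == m.cell_ids
        np.testing.assert_array_equal(trimmed.to_dense(), m.to_dense())

    def test_keep_frac_equals_one_minus_alpha(self):
        rng = np.random.default_rng(1)
        m, cl = one_cluster(rng.normal(size=(6, 30)))
        res, _ = trim_dist(m, cl, knn_k=5, keep_frac=0.9)
        nd = compute_min_knn_distance(m, cl, k=5)
        direct = trim_cells(nd, cl, alpha=0.1)
        assert (res.flags == direct.flags).all()
        assert res.thresholds == direct.thresholds

    def test_planted_outlier_overlap_beats_chance(self, planted, planted_norm):
        res, _ = trim_dist(planted_norm, planted.clusters, knn_k=15,
                           keep_frac=0.9)
        flagged = set(res.extreme_ids)
        truth = set(planted.outlier_flags.index[planted.outlier_flags])
        overlap = len(flagged & truth) / max(len(flagged), 1)
        assert overlap > planted.params.border_frac  # chance level


class TestInvariances:
    def setup_method(self):
        rng = np.random.default_rng(21)
        self.X = rng.normal(size=(10, 40))
        self.m, self.cl = one_cluster(self.X)
        self.nd = compute_min_knn_distance(self.m, self.cl, k=6)

    def test_translation_and_rotation_invariance(self):
        from scipy.stats import ortho_group
        Q = ortho_group.rvs(10, random_state=1)
        shifted = self.X + np.full((10, 1), 3.7)
        rotated = Q @ self.X
        for Y in (shifted, rotated):
            m2, cl2 = one_cluster(Y)
            nd2 = compute_min_knn_distance(m2, cl2, k=6)
            np.testing.assert_allclose(nd2.min_dist, self.nd.min_dist,
                                       atol=1e-9)

    def test_scale_equivariance(self):
        m2, cl2 = one_cluster(2.5 * self.X)
        nd2 = compute_min_knn_distance(m2, cl2, k=6)
        np.testing.assert_allclose(nd2.min_dist, 2.5 * self.nd.min_dist,
                                   rtol=1e-12)
        f1 = trim_cells(self.nd, self.cl, 0.2).flags
        f2 = trim_cells(nd2, cl2, 0.2).flags
        assert (f1.to_numpy() == f2.to_numpy()).all()


def test_quantile_type7_matches_interpolation_formula():
    vals = np.array([1.0, 2.0, 4.0, 8.0])
    # h = (n-1)q; floor/ceil interpolation
    for q in (0.0, 0.25, 0.4, 0.9, 1.0):
        h = 3 * q
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        expected = vals[lo] + (h - lo) * (vals[hi] - vals[lo])
        assert quantile_type7(vals, q) == pytest.approx(expected)
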