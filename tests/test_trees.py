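import numpy as np
import pytest

from humgut import (
    DistanceMatrix,
    normalized_rf,
    phylosymbiosis_test,
    random_topology,
    read_newick,
    rooted_clusters,
    rooted_rf,
    upgma,
)
from humgut.trees import shuffled_labels_topology


def cluster_heights(tree):
    """frozenset(leaves under node) -> node height, for internal nodes."""
    out = {}
    for node in tree.non_tips(include_self=True):
        leaves = list(node.tips())
        depth_below = 0.0
        x = leaves[0]
        while x is not node:
            depth_below += x.length
            x = x.parent
        out[frozenset(t.name for t in leaves)] = depth_below
    return out


class TestUPGMA:
    def test_two_leaves(self):
        dm = DistanceMatrix(["A", "B"], [[0, 3], [3, 0]])
        tree = upgma(dm)
        ch = cluster_heights(tree)
        assert ch[frozenset("AB")] == pytest.approx(1.5)

    def test_three_leaf_hand_example(self):
        # d(A,B)=2, d(A,C)=8, d(B,C)=4: join (A,B) at height 1,
        # then join with C at (8+4)/2 / 2 = 3
        dm = DistanceMatrix(["A", "B", "C"], [[0, 2, 8], [2, 0, 4], [8, 4, 0]])
        ch = cluster_heights(upgma(dm))
        assert ch[frozenset("AB")] == pytest.approx(1.0)
        assert ch[frozenset("ABC")] == pytest.approx(3.0)

    def test_ultrametric(self, rng):
        n = 7
        m = rng.random((n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        tree = upgma(DistanceMatrix([f"L{i}" for i in range(n)], d))
        depths = [tree.distance(t) for t in tree.tips()]
        assert np.allclose(depths, depths[0], atol=1e-9)

    def test_deterministic_under_ties(self):
        d = 1 - np.eye(4)  # every merge distance tied
        dm = DistanceMatrix(list("DCBA"), d)
        t1, t2 = upgma(dm), upgma(dm)
        assert str(t1) == str(t2)
        # lexicographic tie-break merges A,B first
        assert frozenset("AB") in cluster_heights(t1)

    def test_matches_scipy_average_linkage(self, rng):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        for _ in range(20):
            n = 6
            m = rng.random((n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0)
            tree = upgma(DistanceMatrix([f"L{i}" for i in range(n)], d))
            heights = sorted(cluster_heights(tree).values())
            z = average(squareform(d, checks=False))
            assert np.allclose(heights, sorted(z[:, 2] / 2), atol=1e-10)

    def test_single_label_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            upgma(DistanceMatrix(["A"], [[0.0]]))


class TestRootedClusters:
    def test_balanced_four_leaves(self):
        t = read_newick("((a,b),(c,d));")
        assert rooted_clusters(t) == {frozenset("ab"), frozenset("cd")}

    def test_caterpillar_four_leaves(self):
        t = read_newick("(((a,b),c),d);")
        assert rooted_clusters(t) == {frozenset("ab"), frozenset("abc")}

    def test_star_tree_has_no_clusters(self):
        t = read_newick("(a,b,c,d);")
        assert rooted_clusters(t) == set()


class TestRootedRF:
    def test_identical_trees(self):
        t = read_newick("((a,b),(c,d));")
        u = read_newick("((a,b),(c,d));")
        assert rooted_rf(t, u) == 0
        assert normalized_rf(t, u) == 0.0

    def test_four_leaf_hand_example(self):
        t = read_newick("((a,b),(c,d));")
        u = read_newick("(((a,b),c),d);")
        assert rooted_rf(t, u) == 2  # {c,d} vs {a,b,c}
        assert normalized_rf(t, u) == pytest.approx(0.5)

    def test_cluster_disjoint_binary_trees(self):
        # no shared non-trivial cluster on 5 leaves -> rf = 2(n-2) = 6, nrf = 1
        t = read_newick("((((a,b),c),d),e);")
        u = read_newick("((((c,d),e),a),b);")
        assert rooted_clusters(t) & rooted_clusters(u) == set()
        assert rooted_rf(t, u) == 6
        assert normalized_rf(t, u) == 1.0

    def test_leaf_mismatch_errors(self):
        t = read_newick("((a,b),c);")
        u = read_newick("((a,b),d);")
        with pytest.raises(ValueError, match="leaf sets differ"):
            rooted_rf(t, u)

    def test_star_trees_normalize_to_zero(self):
        t = read_newick("(a,b,c,d);")
        u = read_newick("(a,b,c,d);")
        assert normalized_rf(t, u) == 0.0


class TestRandomTopology:
    def test_two_labels(self):
        t = random_topology(["a", "b"], seed=0)
        assert {x.name for x in t.tips()} == {"a", "b"}

    def test_deterministic(self):
        a = random_topology(list("abcdef"), seed=9)
        b = random_topology(list("abcdef"), seed=9)
        assert str(a) == str(b)

    def test_three_leaf_topologies_uniform(self):
        # 3 rooted topologies, each should appear with frequency 1/3
        n = 900
        counts = {}
        for k in range(n):
            t = random_topology(["a", "b", "c"], seed=k)
            (cherry,) = rooted_clusters(t)
            counts[cherry] = counts.get(cherry, 0) + 1
        assert len(counts) == 3
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        for c in counts.values():
            assert abs(c / n - 1 / 3) <= 3 * se

    def test_shuffled_labels_preserves_shape(self):
        t = read_newick("(((a,b),c),(d,e));")
        s = shuffled_labels_topology(t, seed=4)
        assert sorted(len(c) for c in rooted_clusters(s)) == sorted(
            len(c) for c in rooted_clusters(t)
        )
        assert {x.name for x in s.tips()} == {"a", "b", "c", "d", "e"}


class TestPhylosymbiosisTest:
    def test_identical_trees_give_p_by_formula(self):
        host = read_newick("(((a,b),c),(d,e));")
        res = phylosymbiosis_test(host.copy(), host, n_random=200, seed=0)
        assert res.observed_nrf == 0.0
        k = int(np.sum(res.null_scores <= 0))
        assert res.p_value == pytest.approx((1 + k) / 201)
        assert res.p_value_plain == pytest.approx(k / 200)

    def test_three_leaf_null_is_bernoulli_third(self):
        host = read_newick("((a,b),c);")
        res = phylosymbiosis_test(host.copy(), host, n_random=900, seed=1)
        assert set(np.unique(res.null_scores)) <= {0.0, 1.0}
        prop0 = np.mean(res.null_scores == 0)
        se = np.sqrt((1 / 3) * (2 / 3) / 900)
        assert abs(prop0 - 1 / 3) <= 3 * se

    def test_null_count_and_errors(self):
        host = read_newick("((a,b),(c,d));")
        res = phylosymbiosis_test(host.copy(), host, n_random=50, seed=2)
        assert len(res.null_scores) == 50
        with pytest.raises(ValueError, match="n_random"):
            phylosymbiosis_test(host.copy(), host, n_random=0, seed=2)
        other = read_newick("((a,b),(c,e));")
        with pytest.raises(ValueError, match="leaf sets differ"):
            phylosymbiosis_test(other, host, n_random=10, seed=2)

    def test_label_shuffle_null(self):
        host = read_newick("(((a,b),c),(d,e));")
        res = phylosymbiosis_test(
            host.copy(), host, n_random=100, seed=3, null="label_shuffle"
        )
        assert len(res.null_scores) == 100
        assert res.observed_nrf == 0.0
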