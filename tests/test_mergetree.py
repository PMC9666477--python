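import numpy as np
import pytest

import treehet as th
from treehet.errors import DataError, IntegrityError, NewickParseError, ScalingError
from treehet.simulate import random_merge_tree

from conftest import cherry


def naive_average_linkage(D):
    """O(n^3) text-book agglomeration oracle (unweighted average update)."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    parent = -np.ones(2 * n - 1, dtype=np.int64)
    height = np.zeros(2 * n - 1)
    node_of = {i: i for i in range(n)}
    nxt = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        parent[node_of[a]] = parent[node_of[b]] = nxt
        height[nxt] = d
        clusters[a] = clusters[a] + clusters.pop(b)
        node_of[a] = nxt
        nxt += 1
    for i in range(1, n - 1):
        height[n + i] = max(height[n + i], height[n + i - 1])
    return th.MergeTree(parent, height)


class TestPointCloudAndDistances:
    def test_cloud_extraction_sizes(self):
        cohort = th.simulate_radiomic_table(6, seed=0)
        table = th.z_normalize(th.impute_missing(cohort.table))
        reduced = th.view_aware_pca(table, cohort.schema)
        total = 0
        for pid in reduced.patients:
            cloud = th.patient_point_cloud(reduced, pid)
            assert cloud.points.shape[1] == 12
            total += cloud.n_lesions
        assert total == reduced.n_lesions  # clouds partition the rows

    def test_unknown_patient_raises(self):
        cohort = th.simulate_radiomic_table(3, seed=0)
        table = th.z_normalize(th.impute_missing(cohort.table))
        reduced = th.view_aware_pca(table, cohort.schema)
        with pytest.raises(KeyError):
            th.patient_point_cloud(reduced, "nobody")

    def test_three_four_five(self):
        D = th.lesion_distance_matrix(th.PointCloud("p", np.array([[0, 0], [3, 4.0]])))
        assert D[0, 1] == pytest.approx(5.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(5, 12))
        D = th.lesion_distance_matrix(th.PointCloud("p", pts))
        for i in range(5):
            for j in range(5):
                assert D[i, j] == pytest.approx(np.linalg.norm(pts[i] - pts[j]))


class TestAverageLinkage:
    def test_worked_example_heights(self, tree_012):
        assert sorted(tree_012.height) == pytest.approx([0, 0, 0, 1.0, 9.5])
        assert tree_012.n_leaves == 3
        assert tree_012.total_weight() == pytest.approx(20.0)

    def test_two_points_cherry(self):
        t = th.average_linkage_dendrogram(np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert t.root_height == pytest.approx(3.0)
        assert t.n_leaves == 2

    def test_identical_points_merge_at_zero(self):
        t = th.average_linkage_dendrogram(np.zeros((4, 4)))
        assert t.root_height == 0.0

    def test_single_point_tree(self):
        t = th.average_linkage_dendrogram(np.zeros((1, 1)), labels=["x"])
        assert t.n_vertices == 1 and t.root_height == 0.0

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(IntegrityError):
            th.average_linkage_dendrogram(D)

    @pytest.mark.parametrize("n", [2, 4, 6, 8])
    def test_agrees_with_naive_oracle(self, n):
        rng = np.random.default_rng(n)
        pts = rng.normal(size=(n, 3))
        D = th.lesion_distance_matrix(th.PointCloud("p", pts))
        ours = th.average_linkage_dendrogram(D)
        oracle = naive_average_linkage(D)
        assert ours.canonical_form() == oracle.canonical_form()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(7, 4))
        perm = rng.permutation(7)
        t1 = th.average_linkage_dendrogram(
            th.lesion_distance_matrix(th.PointCloud("p", pts)))
        t2 = th.average_linkage_dendrogram(
            th.lesion_distance_matrix(th.PointCloud("p", pts[perm])))
        assert t1.canonical_form() == t2.canonical_form()


class TestRescale:
    def test_global_preserves_ratios(self):
        trees = [cherry(5.0, 5.0), cherry(10.0, 10.0)]
        out = th.rescale_heights(trees, "global")
        assert [t.root_height for t in out] == pytest.approx([0.5, 1.0])

    def test_per_tree_all_roots_one(self):
        trees = [cherry(5.0, 5.0), cherry(10.0, 10.0)]
        out = th.rescale_heights(trees, "per_tree")
        assert [t.root_height for t in out] == pytest.approx([1.0, 1.0])

    def test_self_normalization(self, tree_012):
        out = th.rescale_heights([tree_012], "global")
        assert out[0].root_height == pytest.approx(1.0)

    def test_all_zero_heights_error(self):
        flat = th.average_linkage_dendrogram(np.zeros((3, 3)))
        with pytest.raises(ScalingError):
            th.rescale_heights([flat], "global")


class TestHeightCurve:
    def test_worked_counts(self, tree_012):
        curve = th.height_count_curve(tree_012, [0.5, 5.0, 10.0])
        assert list(curve.counts) == [2, 1, 0]

    def test_single_leaf_identically_zero(self):
        t = th.MergeTree(np.array([-1]), np.array([0.0]))
        assert list(th.height_count_curve(t, [0.0, 1.0]).counts) == [0, 0]

    def test_monotone_on_random_trees(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = random_merge_tree(int(rng.integers(1, 10)), seed=rng)
            grid = np.linspace(0, t.root_height * 1.2, 25)
            counts = th.height_count_curve(t, grid).counts
            assert (np.diff(counts) <= 0).all()


class TestPrune:
    def test_worked_example_tree_012(self, tree_012, cherry95):
        out = th.prune(tree_012, 1.0, 0)
        assert out.canonical_form() == cherry95.canonical_form()

    def test_eps_zero_positive_weights_unchanged(self, tree_012):
        out = th.prune(tree_012, 0.0, 0)
        assert out.canonical_form() == tree_012.canonical_form()

    def test_cherry_mixed_case_keeps_root(self):
        out = th.prune(cherry(1.0, 3.0), 2.0, 0)
        assert out.n_vertices == 2  # root retained above the surviving leaf
        assert out.total_weight() == pytest.approx(3.0)

    def test_negative_eps_rejected(self, tree_012):
        with pytest.raises(ValueError):
            th.prune(tree_012, -0.1)

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            t = random_merge_tree(int(rng.integers(1, 9)), seed=rng)
            prev = None
            for eps in np.linspace(0, 1.1 * max(t.root_height, 0.1), 6):
                p = th.prune(t, eps, 7)
                assert th.prune(p, eps, 8).canonical_form() == p.canonical_form()
                assert p.n_leaves >= 1
                assert p.total_weight() <= t.total_weight() + 1e-9
                if prev is not None:
                    assert p.n_leaves <= prev
                prev = p.n_leaves

    def test_tie_break_is_canonical_regardless_of_seed(self):
        t = cherry(2.0, 2.0)
        forms = {th.prune(t, 2.0, s).canonical_form() for s in range(5)}
        assert len(forms) == 1  # equal-weight siblings: any keep is isomorphic


class TestNewick:
    def test_cherry_string(self):
        s = th.to_newick(cherry(1.0, 1.0))
        assert s.count(":1") == 2 and s.endswith(";")

    def test_round_trip_random_trees(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            t = random_merge_tree(int(rng.integers(1, 10)), seed=rng)
            back = th.from_newick(th.to_newick(t))
            assert back.canonical_form() == t.canonical_form()
            assert sorted(filter(None, back.labels)) == sorted(filter(None, t.labels))

    def test_malformed_newick_raises(self):
        with pytest.raises(NewickParseError):
            th.from_newick("((a:1,b:2;")

    def test_missing_branch_length_raises(self):
        with pytest.raises(NewickParseError):
            th.from_newick("(a,b:1);")
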