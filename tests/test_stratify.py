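import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import treehet as th
from treehet.errors import CapacityError, DataError
from treehet.simulate import random_merge_tree


def block_matrix(sizes, within=0.1, between=2.0, seed=0):
    """Distance matrix of well-separated blocks plus jitter."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    n = len(labels)
    D = np.where(labels[:, None] == labels[None, :], within, between)
    D = D + rng.uniform(0, 0.01, size=(n, n))
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D, labels


class TestWardCluster:
    def test_two_blocks_high_silhouette(self):
        D, truth = block_matrix([8, 8])
        res = th.ward_cluster(D)
        assert res.k == 2 and res.silhouette > 0.9
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_three_blocks(self):
        D, truth = block_matrix([6, 6, 6])
        res = th.ward_cluster(D)
        assert res.k == 3
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_zero_matrix_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = th.ward_cluster(np.zeros((6, 6)))
        assert res.k == 2

    def test_patient_order_invariance(self):
        D, _ = block_matrix([5, 5, 5], seed=1)
        rng = np.random.default_rng(2)
        perm = rng.permutation(D.shape[0])
        a = th.ward_cluster(D)
        b = th.ward_cluster(D[np.ix_(perm, perm)])
        assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0

    def test_too_few_patients(self):
        with pytest.raises(CapacityError):
            th.ward_cluster(np.zeros((2, 2)))

    def test_selection_trace_reported(self):
        D, truth = block_matrix([6, 6, 6])
        res = th.ward_cluster(pd.DataFrame(D), response=truth)
        assert set(res.trace["k"]) == {2, 3, 4, 5}
        assert res.trace["silhouette"].notna().all()
        assert res.trace["mutual_information"].notna().all()


class TestDBSCAN:
    def test_scattered_patients_marked_noise(self):
        D, _ = block_matrix([8, 8], within=0.1, between=2.0, seed=3)
        n = D.shape[0]
        # append 3 patients far from everything and from each other
        m = n + 3
        full = np.full((m, m), 5.0)
        full[:n, :n] = D
        full[n:, n:] = np.array([[0, 6, 7], [6, 0, 8], [7, 8, 0.0]])
        np.fill_diagonal(full, 0.0)
        labels, report = th.dbscan_noise_check(full, eps=0.5, min_samples=3)
        assert report["n_noise"] == 3
        assert (np.asarray(labels[-3:]) == -1).all()

    def test_all_identical_single_cluster(self):
        labels, report = th.dbscan_noise_check(np.zeros((6, 6)), eps=0.5, min_samples=2)
        assert report["n_noise"] == 0 and report["n_clusters"] == 1

    def test_eps_below_min_distance_all_noise(self):
        D, _ = block_matrix([4, 4], within=1.0, between=2.0)
        labels, report = th.dbscan_noise_check(D, eps=0.01, min_samples=2)
        assert report["n_noise"] == 8


class TestBaselines:
    @staticmethod
    def _reduced_from(points, patient_ids, lesion_ids):
        return th.ReducedMatrix(
            pd.Series(patient_ids), pd.Series(lesion_ids),
            np.asarray(points, dtype=float),
            [f"c{i}" for i in range(np.asarray(points).shape[1])], {}, {},
        )

    def test_single_lesion_patients_equal_all_lesion_clustering(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(0, 0.1, (5, 3)), rng.normal(5, 0.1, (5, 3))])
        red = self._reduced_from(pts, [f"P{i}" for i in range(10)], ["L0"] * 10)
        big = th.baseline_biggest_lesion(red, volumes=np.ones(10))
        mean = th.baseline_mean_vector(red)
        assert adjusted_rand_score(big.labels, mean.labels) == 1.0
        assert big.k == mean.k == 2

    def test_tied_volumes_take_lowest_lesion_id(self):
        pts = [[0.0, 0.0], [9.0, 9.0], [1.0, 1.0]]
        red = self._reduced_from(pts, ["P1", "P1", "P2"], ["L1", "L2", "L1"])
        frame = red.to_frame().assign(_volume=[2.0, 2.0, 1.0])
        frame = frame.sort_values(["patient_id", "_volume", "lesion_id"],
                                  ascending=[True, False, True], kind="mergesort")
        top = frame.groupby("patient_id").first()
        assert top.loc["P1", "lesion_id"] == "L1"  # tie -> lowest lesion id

    def test_missing_volumes_rejected(self):
        red = self._reduced_from([[0.0], [1.0]], ["P1", "P2"], ["L0", "L0"])
        with pytest.raises(DataError):
            th.baseline_biggest_lesion(red, volumes=np.array([1.0, np.nan]))

    def test_mean_of_symmetric_cloud_is_origin(self):
        pts = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 2.0], [0.0, -2.0]])
        red = self._reduced_from(pts, ["P1"] * 4, ["L0", "L1", "L2", "L3"])
        mean = red.to_frame().groupby("patient_id")[red.columns].mean()
        np.testing.assert_allclose(mean.to_numpy(), 0.0, atol=1e-12)


class TestComparePartitions:
    def test_identical_and_relabelled(self):
        a = np.array([0, 0, 1, 1, 2])
        assert th.compare_partitions(a, a) == 1.0
        assert th.compare_partitions(a, (a + 1) % 3) == 1.0

    def test_worked_pair_count(self):
        # 6 pairs: only (1,3) and (2,4)... -> 2 agreements out of 6
        assert th.compare_partitions([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(1 / 3)

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.integers(0, 3, size=12)
            b = rng.integers(0, 4, size=12)
            agree = sum(
                (a[i] == a[j]) == (b[i] == b[j])
                for i in range(12) for j in range(i + 1, 12)
            )
            assert th.compare_partitions(a, b) == pytest.approx(agree / 66)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            th.compare_partitions([0, 1], [0, 1, 2])


class TestCharacterize:
    def test_location_shift_detected_with_power(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(40):
            clinical = pd.DataFrame({
                "psa": np.concatenate([rng.normal(0, 1, 20), rng.normal(2, 1, 20)]),
            }, index=[f"P{i}" for i in range(40)])
            labels = np.repeat([0, 1], 20)
            rep = th.characterize_clusters(labels, clinical, alpha=0.1)
            loc = rep[rep["family"] == "mean/distribution"]
            hits += bool((loc["p_two_sided"] < 0.1).all())
        assert hits >= 38  # power >= 95% at a 2-sigma shift

    def test_constant_variable_degenerate_but_defined(self):
        clinical = pd.DataFrame({"flat": np.ones(20)}, index=[f"P{i}" for i in range(20)])
        labels = np.repeat([0, 1], 10)
        rep = th.characterize_clusters(labels, clinical, alpha=0.1,
                                       categorical=())
        assert rep["p_two_sided"].between(0, 1).all()
        assert not rep["significant"].any()

    def test_small_group_falls_back_nonparametric(self):
        clinical = pd.DataFrame({"x": np.arange(8.0)}, index=[f"P{i}" for i in range(8)])
        labels = np.array([0, 0, 1, 1, 1, 1, 1, 1])
        with pytest.warns(UserWarning, match="Shapiro"):
            rep = th.characterize_clusters(labels, clinical, alpha=0.1, categorical=())
        assert (rep.loc[rep["family"] == "mean/distribution", "test"] == "mann-whitney").all()

    def test_categorical_chi2(self):
        rng = np.random.default_rng(7)
        clinical = pd.DataFrame({
            "skeleton": np.concatenate([rng.random(30) < 0.9, rng.random(30) < 0.1]).astype(int)
        }, index=[f"P{i}" for i in range(60)])
        labels = np.repeat([0, 1], 30)
        rep = th.characterize_clusters(labels, clinical, alpha=0.1)
        assert (rep["family"] == "independence").all()
        assert (rep["p_two_sided"] < 0.1).all()

    def test_bh_adjustment_column(self):
        rng = np.random.default_rng(8)
        clinical = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)},
                                index=[f"P{i}" for i in range(30)])
        rep = th.characterize_clusters(np.repeat([0, 1], 15), clinical, bh_adjust=True)
        assert "p_adjusted" in rep.columns
        ok = rep["p_adjusted"].notna()
        assert (rep.loc[ok, "p_adjusted"] >= rep.loc[ok, "p_two_sided"] - 1e-12).all()


class TestGroupHeightCurves:
    def test_identical_trees_no_signal(self):
        t = random_merge_tree(5, seed=9)
        trees = [t] * 12
        labels = np.repeat([0, 1], 6)
        out = th.group_height_curves(trees, labels, np.linspace(0, t.root_height, 10),
                                     n_permutations=99, rng_seed=0)
        assert (out.p_pointwise > 0.5).all()
        assert np.allclose(out.f_statistic, 0.0)

    def test_taller_group_detected_mid_heights(self):
        rng = np.random.default_rng(10)
        short = [random_merge_tree(6, lambda r: r.uniform(0.1, 0.3), seed=rng)
                 for _ in range(10)]
        tall = [random_merge_tree(6, lambda r: r.uniform(0.5, 1.0), seed=rng)
                for _ in range(10)]
        labels = np.array([0] * 10 + [1] * 10)
        grid = np.linspace(0, 3.0, 15)
        out = th.group_height_curves(short + tall, labels, grid,
                                     n_permutations=199, rng_seed=0)
        assert out.p_adjusted.min() < 0.05
        # group means inherit the monotone non-increasing shape
        for g in out.means.index:
            assert (np.diff(out.means.loc[g]) <= 1e-9).all()


class TestKMLogrank:
    def test_no_events_flat_curves(self):
        out = th.km_logrank(np.repeat([0, 1], 10), np.ones(20) * 5.0, np.zeros(20))
        for curve in out["curves"].values():
            assert np.allclose(curve.to_numpy(), 1.0)

    def test_identical_groups_large_p(self):
        rng = np.random.default_rng(11)
        time = rng.exponential(5.0, size=60)
        out = th.km_logrank(np.repeat([0, 1], 30), time, np.ones(60))
        assert out["p_value"] > 0.01

    def test_early_events_vs_censored_small_p(self):
        rng = np.random.default_rng(12)
        time = np.concatenate([rng.exponential(1.0, 30), np.full(30, 20.0)])
        event = np.concatenate([np.ones(30), np.zeros(30)])
        out = th.km_logrank(np.repeat([0, 1], 30), time, event)
        assert out["p_value"] < 1e-4
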