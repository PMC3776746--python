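import numpy as np
import pytest

from ahmo.graphs import correlation_graph, fisher_z_standardize, group_average
from ahmo.parcellation import (ModularityModel, build_roi_voxel_graph,
                               exhaustive_best_partition,
                               merge_small_clusters, modularity,
                               optimize_modularity, repair_contiguity,
                               run_ahmo)
from ahmo.volumes import LabelVolume, Partition, TimeSeriesVolume

from conftest import TOY_MIN_SIZE, random_weighted_graph


def two_cliques():
    W = np.zeros((6, 6))
    for a, b in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
        W[a, b] = W[b, a] = 1.0
    return ModularityModel(W=W)


def modularity_oracle(W, labels):
    """Direct double-loop evaluation of Q over ordered pairs."""
    s = W.sum(axis=1)
    V = W.sum()
    q = 0.0
    for i in range(len(W)):
        for j in range(len(W)):
            if labels[i] == labels[j]:
                q += W[i, j] - s[i] * s[j] / V
    return q / V


class TestModularity:
    def test_two_cliques_partition_scores_half(self):
        assert modularity(two_cliques(), np.array([0, 0, 0, 1, 1, 1])) \
            == pytest.approx(0.5, abs=1e-12)

    def test_single_cluster_is_zero(self):
        rng = np.random.default_rng(0)
        W = random_weighted_graph(rng, 7)
        m = ModularityModel(W=W)
        assert modularity(m, np.zeros(7, dtype=int)) == pytest.approx(0.0, abs=1e-12)

    def test_any_split_of_complete_uniform_graph_is_negative(self):
        W = np.ones((5, 5)) - np.eye(5)
        m = ModularityModel(W=W)
        for split in ([0, 0, 0, 0, 1], [0, 0, 0, 1, 1], [0, 1, 0, 1, 0]):
            assert modularity(m, np.array(split)) < 0
        _, q = exhaustive_best_partition(m)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            W = random_weighted_graph(rng, 6)
            if W.sum() == 0:
                continue
            m = ModularityModel(W=W)
            labels = rng.integers(0, 3, size=6)
            assert modularity(m, labels) == pytest.approx(
                modularity_oracle(W, labels), abs=1e-12)

    def test_range_invariant(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            W = random_weighted_graph(rng, 6)
            if W.sum() == 0:
                continue
            m = ModularityModel(W=W)
            q = modularity(m, rng.integers(0, 6, size=6))
            assert -1.0 <= q <= 1.0


class TestOptimizer:
    def test_recovers_two_cliques(self):
        m = two_cliques()
        labels = optimize_modularity(m, seed=3)
        assert modularity(m, labels) == pytest.approx(0.5, abs=1e-12)
        assert len(np.unique(labels)) == 2

    def test_single_node(self):
        m = ModularityModel(W=np.zeros((1, 1)))
        assert optimize_modularity(m, seed=0).tolist() == [0]

    def test_planted_two_block_graph_recovered_exactly(self):
        rng = np.random.default_rng(4)
        n = 20
        W = np.full((n, n), 0.05)
        W[:10, :10] = 1.0
        W[10:, 10:] = 1.0
        W = W * (1 - np.eye(n))
        W = 0.5 * (W + W.T)
        labels = optimize_modularity(ModularityModel(W=W), seed=5)
        truth = np.array([0] * 10 + [1] * 10)
        assert len(np.unique(labels)) == 2
        assert (labels[:10] == labels[0]).all() and (labels[10:] == labels[10]).all()
        assert labels[0] != labels[10]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        W = random_weighted_graph(rng, 15)
        m = ModularityModel(W=W)
        a = optimize_modularity(m, seed=42)
        b = optimize_modularity(m, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_matches_exhaustive_search_on_small_graphs(self):
        """Spot-check optimality against Bell-number enumeration (n <= 8)."""
        rng = np.random.default_rng(7)
        for trial in range(20):
            n = int(rng.integers(2, 9))
            W = random_weighted_graph(rng, n)
            if W.sum() == 0:
                continue
            m = ModularityModel(W=W)
            q = modularity(m, optimize_modularity(m, seed=trial))
            _, q_best = exhaustive_best_partition(m)
            assert q == pytest.approx(q_best, abs=1e-10)

    def test_returned_q_never_negative(self):
        rng = np.random.default_rng(8)
        for trial in range(10):
            W = random_weighted_graph(rng, 10)
            if W.sum() == 0:
                continue
            m = ModularityModel(W=W)
            assert modularity(m, optimize_modularity(m, seed=trial)) >= 0


class TestContiguityRepair:
    def test_separated_blobs_become_two_clusters(self):
        labels = np.zeros((7, 3, 3), dtype=int)
        labels[0:2] = 1
        labels[5:7] = 1
        out = repair_contiguity(Partition(labels=labels))
        assert out.n_clusters == 2

    def test_contiguous_partition_unchanged_up_to_relabeling(self):
        labels = np.zeros((6, 3, 3), dtype=int)
        labels[:3] = 1
        labels[3:] = 2
        out = repair_contiguity(Partition(labels=labels))
        assert out.n_clusters == 2
        # voxel membership identical, only label values may change
        for cid in (1, 2):
            vals = np.unique(out.labels[labels == cid])
            assert vals.size == 1 and vals[0] > 0

    def test_diagonal_touch_depends_on_connectivity(self):
        labels = np.zeros((2, 2, 2), dtype=int)
        labels[0, 0, 0] = 1
        labels[1, 1, 1] = 1  # touches only corner-diagonally
        assert repair_contiguity(Partition(labels=labels), 6).n_clusters == 2
        assert repair_contiguity(Partition(labels=labels), 26).n_clusters == 1

    def test_matches_connected_components_oracle(self):
        from scipy import ndimage

        rng = np.random.default_rng(9)
        labels = (rng.random((8, 8, 4)) < 0.4).astype(int)
        out = repair_contiguity(Partition(labels=labels), 6)
        _, n_comp = ndimage.label(labels > 0)
        assert out.n_clusters == n_comp


class TestMergeSmallClusters:
    def _three_cluster_partition(self):
        """10-voxel cluster with a nearer 100-voxel and a farther 200-voxel one."""
        labels = np.zeros((31, 10, 1), dtype=int)
        labels[0:1] = 1          # 10 voxels at x=0
        labels[1:11] = 2         # 100 voxels at x=1..10 (centroid x=5.5)
        labels[11:31] = 3        # 200 voxels at x=11..30 (centroid x=20.5)
        parent = LabelVolume(labels=np.ones_like(labels))
        return Partition(labels=labels, parent=parent)

    def test_small_cluster_merges_into_nearest_centroid(self):
        out = merge_small_clusters(self._three_cluster_partition(),
                                   min_size=50, voxel_dims=np.ones(3))
        assert out.sizes() == {2: 110, 3: 200}

    def test_all_clusters_large_is_identity(self):
        p = self._three_cluster_partition()
        out = merge_small_clusters(p, min_size=5, voxel_dims=np.ones(3))
        np.testing.assert_array_equal(out.labels, p.labels)

    def test_centroid_tie_goes_to_larger_cluster(self):
        labels = np.zeros((9, 5, 1), dtype=int)
        labels[4] = 1            # 5 voxels at x=4, centroid (4, 2)
        labels[0:4] = 2          # 20 voxels, centroid (1.5, 2): distance 2.5
        labels[5:9, 1:4] = 3     # 12 voxels, centroid (6.5, 2): distance 2.5
        parent = LabelVolume(labels=np.ones_like(labels))
        out = merge_small_clusters(Partition(labels=labels, parent=parent),
                                   min_size=10, voxel_dims=np.ones(3))
        assert out.sizes() == {2: 25, 3: 12}  # tie broken toward the larger

    def test_merge_never_crosses_parent_boundaries(self):
        labels = np.zeros((8, 4, 1), dtype=int)
        labels[0] = 1            # small cluster alone in parent region 1
        parent_labels = np.zeros_like(labels)
        parent_labels[0] = 1
        parent_labels[1:] = 2
        labels[1:] = 2
        parent = LabelVolume(labels=parent_labels)
        out = merge_small_clusters(Partition(labels=labels, parent=parent),
                                   min_size=10, voxel_dims=np.ones(3))
        # the undersized cluster cannot leave its parent ROI; it is kept
        assert out.sizes()[1] == 4
        assert out.cluster_parent()[1] == 1


class TestRoiVoxelGraph:
    def _cohort_with_two_coherent_pairs(self):
        rng = np.random.default_rng(10)
        t = 100
        a = rng.standard_normal(t)
        b = rng.standard_normal(t)
        data = np.zeros((4, 1, 1, t))
        data[0, 0, 0] = a + 0.01 * rng.standard_normal(t)
        data[1, 0, 0] = a + 0.01 * rng.standard_normal(t)
        data[2, 0, 0] = b + 0.01 * rng.standard_normal(t)
        data[3, 0, 0] = b + 0.01 * rng.standard_normal(t)
        vol = TimeSeriesVolume(data=data, tr_seconds=2.0)
        atlas = LabelVolume(labels=np.ones((4, 1, 1), dtype=int))
        return [vol], atlas

    def test_two_coherent_pairs_give_two_strong_blocks(self):
        cohort, atlas = self._cohort_with_two_coherent_pairs()
        model = build_roi_voxel_graph(cohort, atlas, roi=1)
        assert model.W[0, 1] > 10 and model.W[2, 3] > 10
        assert model.W[0, 2] < 5 and model.W[1, 3] < 5

    def test_opposite_subject_correlations_cancel_to_zero(self):
        rng = np.random.default_rng(11)
        t = 80
        x = rng.standard_normal(t)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.standard_normal(t)
        v1 = TimeSeriesVolume(data=np.stack([x, y]).reshape(2, 1, 1, t),
                              tr_seconds=2.0)
        v2 = TimeSeriesVolume(data=np.stack([x, -y]).reshape(2, 1, 1, t),
                              tr_seconds=2.0)
        atlas = LabelVolume(labels=np.ones((2, 1, 1), dtype=int))
        model = build_roi_voxel_graph([v1, v2], atlas, roi=1)
        assert model.W[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_weights_match_graph_pipeline_oracle(self, default_cohort):
        """ROI graph equals corr -> Fisher z -> group mean -> clamp, per element."""
        _, atlas, _, cohort = default_cohort
        roi = int(atlas.region_ids[0])
        model = build_roi_voxel_graph(cohort[:5], atlas, roi)
        mask = atlas.labels == roi
        graphs = []
        for vol in cohort[:5]:
            series = vol.data[mask]
            graphs.append(fisher_z_standardize(correlation_graph(series),
                                               ns=series.shape[1]))
        expected = np.clip(group_average(graphs).weights, 0.0, None)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(model.W, expected, atol=1e-10)


class TestRunAhmo:
    def test_low_noise_recovery_is_exact(self, low_noise_run):
        from sklearn.metrics import adjusted_rand_score

        _, atlas, truth, _, result = low_noise_run
        fg = atlas.labels > 0
        ari = adjusted_rand_score(truth.partition.labels[fg],
                                  result.partition.labels[fg])
        assert ari == pytest.approx(1.0)
        assert result.cluster_count == truth.partition.n_clusters

    def test_nesting_min_size_and_q_invariants(self, default_ahmo, default_cohort):
        _, atlas, _, _ = default_cohort
        part = default_ahmo.partition
        mapping = part.cluster_parent()  # raises if nesting violated
        assert set(mapping.values()) <= set(atlas.region_ids.tolist())
        assert min(part.sizes().values()) >= TOY_MIN_SIZE
        assert all(q >= 0 for q in default_ahmo.per_roi_Q.values())
        # labels are 1..K
        assert part.cluster_ids.tolist() == list(range(1, part.n_clusters + 1))

    def test_deterministic_given_seed(self, default_cohort):
        _, atlas, _, cohort = default_cohort
        a = run_ahmo(cohort[:4], atlas, min_size=TOY_MIN_SIZE, seed=11)
        b = run_ahmo(cohort[:4], atlas, min_size=TOY_MIN_SIZE, seed=11)
        np.testing.assert_array_equal(a.partition.labels, b.partition.labels)

    def test_every_cluster_is_contiguous(self, default_ahmo):
        from scipy import ndimage

        part = default_ahmo.partition
        for cid in part.cluster_ids:
            _, n_comp = ndimage.label(part.labels == cid)
            assert n_comp == 1
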