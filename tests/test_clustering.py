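"""Iterative merge clustering: hand-worked cases, oracle equivalence, invariants."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linprog

import surfchannel as sc
from surfchannel.clustering import CentroidCloud, ClusterParams

from .oracles import brute_converge, brute_pairs


class TestNeighborPairs:
    def test_beyond_cutoff_empty(self):
        assert sc.neighbor_pairs(np.array([[0, 0, 0], [12, 0, 0]]), 10.0) == []

    def test_single_pair(self):
        pairs = sc.neighbor_pairs(np.array([[0, 0, 0], [5, 0, 0]]), 10.0)
        assert len(pairs) == 1
        assert pairs[0][:2] == (0, 1)
        assert pairs[0][2] == pytest.approx(5.0)

    def test_cutoff_is_strict(self):
        assert sc.neighbor_pairs(np.array([[0, 0, 0], [10.0, 0, 0]]), 10.0) == []

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 30, size=(50, 3))
        got = sc.neighbor_pairs(pts, 10.0)
        expected = brute_pairs(pts, 10.0)
        assert [(i, j) for i, j, _ in got] == [(i, j) for i, j, _ in expected]
        np.testing.assert_allclose(
            [d for _, _, d in got], [d for _, _, d in expected], atol=1e-12
        )

    def test_empty_and_singleton(self):
        assert sc.neighbor_pairs(np.empty((0, 3)), 10.0) == []
        assert sc.neighbor_pairs(np.array([[1.0, 2, 3]]), 10.0) == []


class TestClusterIteration:
    def test_single_merge_at_midpoint(self):
        cloud = CentroidCloud(np.array([[0.0, 0, 0], [4.0, 0, 0]]))
        out, rec = sc.cluster_iteration(cloud)
        np.testing.assert_allclose(out.points, [[2.0, 0, 0]])
        assert out.weights.tolist() == [2]
        assert rec.merges == [(0, 1, pytest.approx(4.0))]

    def test_mutually_isolated_pair_removed(self):
        cloud = CentroidCloud(np.array([[0.0, 0, 0], [12.0, 0, 0]]))
        out, rec = sc.cluster_iteration(cloud)
        assert len(out) == 0
        assert rec.dropped == [0, 1]

    def test_collinear_hand_worked_example(self):
        # {0, 4, 8, 40} on x, cutoff 10: tie between (0,4) and (4,8) broken
        # lexicographically -> merge p0,p1 at (2,0,0); p2 carried; p3 isolated.
        cloud = CentroidCloud(np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0], [40.0, 0, 0]]))
        out, rec = sc.cluster_iteration(cloud)
        np.testing.assert_allclose(out.points, [[2.0, 0, 0], [8.0, 0, 0]])
        assert rec.dropped == [3]
        assert rec.carried == [2]
        out2, _ = sc.cluster_iteration(out)
        np.testing.assert_allclose(out2.points, [[5.0, 0, 0]])
        assert out2.weights.tolist() == [3]

    def test_drop_mode_discards_unmatched(self):
        cloud = CentroidCloud(np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]]))
        out, _ = sc.cluster_iteration(cloud, ClusterParams(unmatched="drop"))
        np.testing.assert_allclose(out.points, [[2.0, 0, 0]])

    def test_weighted_average_mode(self):
        cloud = CentroidCloud(np.array([[0.0, 0, 0], [3.0, 0, 0]]),
                              weights=np.array([3, 1]))
        out, _ = sc.cluster_iteration(cloud, ClusterParams(weighted_average=True))
        np.testing.assert_allclose(out.points, [[0.75, 0, 0]])


class TestClusterToConvergence:
    def test_single_point_terminates_immediately(self):
        cloud = CentroidCloud(np.array([[1.0, 2, 3]]))
        clouds, history = sc.cluster_to_convergence(cloud)
        assert len(clouds) == 1
        assert history == []

    def test_two_tight_blobs_converge_to_two_points(self):
        rng = np.random.default_rng(3)
        centers = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        pts = np.vstack([
            c + rng.uniform(-5 / np.sqrt(3), 5 / np.sqrt(3), size=(32, 3))
            for c in centers
        ])
        clouds, _ = sc.cluster_to_convergence(CentroidCloud(pts))
        final = clouds[-1]
        assert len(final) == 2
        for c in centers:
            blob = pts[np.linalg.norm(pts - c, axis=1) < 20]
            d = np.linalg.norm(final.points - blob.mean(axis=0), axis=1).min()
            assert d < 5.0

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_polyline_recovered_outliers_removed(self, seed):
        rng = np.random.default_rng(seed)
        nodes = np.array([[0.0, 0, 0], [30.0, 10, 0], [55.0, 0, 10], [80.0, 5, 5]])
        t = rng.uniform(0, 1, size=400)
        seg = rng.integers(0, len(nodes) - 1, size=400)
        on_line = nodes[seg] + t[:, None] * (nodes[seg + 1] - nodes[seg])
        channel = on_line + rng.normal(scale=2.0, size=(400, 3))
        outliers = rng.uniform(-60, 140, size=(40, 3))
        pts = np.vstack([channel, outliers])
        clouds, _ = sc.cluster_to_convergence(CentroidCloud(pts))
        final = clouds[-1]
        assert len(final) >= 1
        d = sc.distance_to_polyline(final.points, nodes)
        assert d.max() < 6.0
        # >= 90% of outliers vanish: no surviving point carries their origin
        surviving = {o for p in final.origins for o in p}
        kept = sum(1 for k in range(400, 440) if k in surviving)
        assert kept <= 4

    def test_mixed_substrate_types_rejected(self, small_series):
        with pytest.raises(ValueError, match="mixes substrate types"):
            sc.cloud_from_series(small_series)

    def test_frame_window_restricts_pooled_cloud(self, small_series):
        full = sc.cloud_from_series(small_series, "aha")
        window = sc.cloud_from_series(small_series, "aha", frame_range=(0, 10))
        assert len(window) == 10 * 20
        np.testing.assert_allclose(window.points, full.points[: len(window)])

    def test_per_iteration_pdbs_written_and_deterministic(self, tmp_path):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 40, size=(64, 3))
        outs = []
        for d in ("a", "b"):
            out = tmp_path / d
            sc.cluster_to_convergence(CentroidCloud(pts.copy()), output_dir=out,
                                      run_name="x")
            outs.append(sorted(out.iterdir()))
        names_a = [p.name for p in outs[0]]
        assert "x_iter0.pdb" in names_a and "x_iter1.pdb" in names_a
        for pa, pb in zip(*outs):
            assert pa.read_bytes() == pb.read_bytes()


class TestInvariants:
    @pytest.mark.parametrize("seed", range(20))
    def test_full_iterative_result_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 61))
        pts = rng.uniform(0, 30, size=(n, 3))
        clouds, _ = sc.cluster_to_convergence(CentroidCloud(pts.copy()))
        expected = brute_converge(pts, 10.0)
        assert len(clouds) == len(expected)
        for cloud, (epts, ewts) in zip(clouds, expected):
            np.testing.assert_allclose(cloud.points, np.array(epts).reshape(-1, 3),
                                       atol=1e-9)
            assert cloud.weights.tolist() == ewts

    @pytest.mark.parametrize("seed", range(5))
    def test_count_decreases_and_weight_never_increases(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 50, size=(80, 3))
        clouds, history = sc.cluster_to_convergence(CentroidCloud(pts))
        for a, b in zip(clouds, clouds[1:]):
            assert len(b) < len(a)
            assert b.total_weight <= a.total_weight
        for rec in history:
            dists = [d for _, _, d in rec.merges]
            assert all(d < 10.0 for d in dists)
            assert dists == sorted(dists)

    def test_outputs_lie_in_input_convex_hull(self):
        rng = np.random.default_rng(12)
        pts = rng.uniform(0, 15, size=(12, 3))
        clouds, _ = sc.cluster_to_convergence(CentroidCloud(pts.copy()))
        # LP feasibility: q = sum(l_i p_i), l >= 0, sum l = 1
        A_eq = np.vstack([pts.T, np.ones(len(pts))])
        for q in clouds[-1].points:
            res = linprog(np.zeros(len(pts)), A_eq=A_eq,
                          b_eq=np.append(q, 1.0), bounds=(0, 1))
            assert res.success

    def test_iteration_count_is_logarithmic(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 8, size=(256, 3))  # dense: everything merges
        clouds, history = sc.cluster_to_convergence(CentroidCloud(pts))
        carry_stalls = sum(1 for rec in history if rec.carried)
        assert len(history) <= int(np.ceil(np.log2(256))) + carry_stalls
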