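import itertools

import numpy as np
import pytest

from flysin.interaction import InteractionCriteria
from flysin.networks import (MetricZScore, NullModelSpec, betweenness, build_random_networks,
                             closeness, global_efficiency, local_clustering,
                             read_graphml, recording_summary, write_graphml, zscore)
from flysin.synthetic import ArenaSpec, SocialProfile, simulate_trajectories
from flysin.trajectory_io import FlyTrack

from _oracle import (brute_betweenness, brute_closeness_wf, brute_clustering_fagiolo,
                     brute_global_efficiency)
from conftest import graph_from_matrix


def _complete(n, w=1.0):
    W = np.full((n, n), float(w))
    np.fill_diagonal(W, 0)
    return graph_from_matrix(W)


class TestGlobalEfficiency:
    def test_complete_unit_digraph_is_one(self):
        assert global_efficiency(_complete(5)) == pytest.approx(1.0)

    def test_empty_graph_is_zero(self):
        assert global_efficiency(graph_from_matrix(np.zeros((12, 12)))) == 0.0

    def test_weighted_fixture_matches_exhaustive_paths(self):
        W = np.array([[0, 2, 0, 1],
                      [0, 0, 3, 0],
                      [1, 0, 0, 2],
                      [0, 0, 0, 0]], dtype=float)
        g = graph_from_matrix(W)
        assert global_efficiency(g, "count") == pytest.approx(
            brute_global_efficiency(W), abs=1e-12)


class TestClustering:
    def test_directed_three_cycle_matches_closed_formula(self):
        W = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        g = graph_from_matrix(W)
        got = local_clustering(g, "count")
        want = brute_clustering_fagiolo(W)
        for i in range(3):
            assert got[i] == pytest.approx(want[i], abs=1e-12)

    def test_star_hub_is_zero(self):
        W = np.zeros((5, 5))
        W[0, 1:] = 1.0  # hub points at all leaves, no leaf-leaf edges
        g = graph_from_matrix(W)
        assert local_clustering(g, "count")[0] == 0.0

    def test_isolated_node_is_zero(self):
        W = np.zeros((3, 3))
        W[0, 1] = 1.0
        assert local_clustering(graph_from_matrix(W), "count")[2] == 0.0


class TestBetweenness:
    def test_directed_path_middle_node(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 2] = 1.0
        b = betweenness(graph_from_matrix(W), "count")
        assert b[1] == pytest.approx(0.5)  # 1 path through B / (n-1)(n-2)
        assert b[0] == b[2] == 0.0

    def test_complete_digraph_all_zero(self):
        b = betweenness(_complete(5), "count")
        assert all(v == 0.0 for v in b.values())

    def test_five_node_fixture_matches_brute_force(self):
        W = np.array([[0, 1, 2, 0, 0],
                      [0, 0, 3, 0, 1],
                      [0, 0, 0, 1, 0],
                      [2, 0, 0, 0, 2],
                      [0, 0, 1, 0, 0]], dtype=float)
        got = betweenness(graph_from_matrix(W), "count")
        want = brute_betweenness(W)
        for i in range(5):
            assert got[i] == pytest.approx(want[i], abs=1e-9)


class TestCloseness:
    def test_complete_unit_digraph_all_one(self):
        c = closeness(_complete(4), "count")
        assert all(v == pytest.approx(1.0) for v in c.values())

    def test_isolated_node_is_zero(self):
        W = np.zeros((3, 3))
        W[0, 1] = 1.0
        assert closeness(graph_from_matrix(W), "count")[2] == 0.0

    def test_five_node_fixture_matches_brute_distance_matrix(self):
        W = np.array([[0, 1, 0, 0, 2],
                      [0, 0, 2, 0, 0],
                      [3, 0, 0, 1, 0],
                      [0, 0, 0, 0, 1],
                      [0, 2, 0, 0, 0]], dtype=float)
        got = closeness(graph_from_matrix(W), "count")
        want = brute_closeness_wf(W)
        for i in range(5):
            assert got[i] == pytest.approx(want[i], abs=1e-9)

    def test_harmonic_variant_bounded(self):
        c = closeness(_complete(4), "count", variant="harmonic")
        assert all(v == pytest.approx(1.0) for v in c.values())


class TestInvariants:
    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        W = (rng.integers(0, 3, size=(5, 5)) * (rng.random((5, 5)) < 0.6)).astype(float)
        np.fill_diagonal(W, 0)
        perm = np.array([3, 0, 4, 1, 2])
        Wp = W[np.ix_(perm, perm)]
        for fn in (local_clustering, betweenness, closeness):
            a = fn(graph_from_matrix(W), "count")
            b = fn(graph_from_matrix(Wp), "count")
            for new, old in enumerate(perm):
                assert b[new] == pytest.approx(a[old], abs=1e-12)

    def test_weight_scaling_preserves_betweenness(self):
        rng = np.random.default_rng(5)
        W = (rng.integers(1, 4, size=(5, 5)) * (rng.random((5, 5)) < 0.5)).astype(float)
        np.fill_diagonal(W, 0)
        a = betweenness(graph_from_matrix(W), "count")
        b = betweenness(graph_from_matrix(4.0 * W), "count")
        for i in range(5):
            assert b[i] == pytest.approx(a[i], abs=1e-12)

    def test_recording_summary_covers_all_metric_modes(self):
        s = recording_summary(_complete(4))
        assert len(s) == 8
        assert s[("global_efficiency", "count")] == pytest.approx(1.0)


class TestZScore:
    def test_arithmetic(self):
        z = zscore(5.0, [1.0, 2.0, 3.0])
        assert isinstance(z, MetricZScore)
        assert z.null_mean == pytest.approx(2.0) and z.null_sd == pytest.approx(1.0)
        assert z.z == pytest.approx(3.0)

    def test_observation_at_null_mean_is_zero(self):
        assert zscore(2.0, [1.0, 2.0, 3.0]).z == pytest.approx(0.0)

    def test_degenerate_null(self):
        assert zscore(1.0, [1.0, 1.0, 1.0]).z == 0.0
        z = zscore(2.0, [1.0, 1.0, 1.0])
        assert z.undefined and np.isnan(z.z)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            zscore(1.0, [])

    def test_self_distribution_z_moderate(self):
        rng = np.random.default_rng(11)
        null = rng.normal(0, 1, size=10_000)
        zs = [zscore(float(rng.normal()), null).z for _ in range(200)]
        assert np.mean(np.abs(np.array(zs)) < 4) == 1.0


class TestRandomNetworks:
    def test_parked_far_apart_flies_give_empty_nulls(self, criteria):
        # two recordings of stationary flies at distinct far-apart spots
        n, T = 4, 50
        frames = np.arange(T)

        def rec(offset):
            return [FlyTrack(i, frames, np.full(T, offset + 12.0 * i),
                             np.full(T, -20.0 + 40.0 * (i % 2)), np.zeros(T))
                    for i in range(n)]

        nets = build_random_networks([rec(-25.0), rec(-19.0)],
                                     NullModelSpec(n_random_networks=10, group_size=4),
                                     criteria, 30.0, rng=0)
        assert all(g.number_of_edges() == 0 for g in nets)

    def test_seeded_runs_identical(self, criteria, arena):
        recs = [simulate_trajectories(ArenaSpec(duration_s=5.0), 4, SocialProfile(), seed=s)
                for s in (1, 2)]
        spec = NullModelSpec(n_random_networks=3, group_size=4)
        a = build_random_networks(recs, spec, criteria, 30.0, rng=9)
        b = build_random_networks(recs, spec, criteria, 30.0, rng=9)
        for ga, gb in zip(a, b):
            assert sorted(ga.edges(data=True)) == sorted(gb.edges(data=True))

    def test_single_recording_rejected(self, criteria):
        recs = [simulate_trajectories(ArenaSpec(duration_s=2.0), 4, SocialProfile(), seed=0)]
        with pytest.raises(ValueError):
            build_random_networks(recs, NullModelSpec(n_random_networks=1, group_size=2),
                                  criteria, 30.0, rng=0)

    def test_chimeras_never_single_recording(self, criteria):
        # recordings with distinct parked positions let us identify the source:
        # recording 0 flies sit on the left, recording 1 flies on the right
        n, T = 3, 10
        frames = np.arange(T)
        recs = []
        for side in (-20.0, 20.0):
            recs.append([FlyTrack(i, frames, np.full(T, side + i), np.full(T, side),
                                  np.zeros(T)) for i in range(n)])
        nets = build_random_networks(recs, NullModelSpec(n_random_networks=20, group_size=3),
                                     criteria, 30.0, rng=2)
        # a chimera drawn entirely from one recording would co-locate all 3 flies
        # within a few mm and generate edges; mixed chimeras sit 40 mm apart
        assert all(g.number_of_edges() == 0 for g in nets)


def test_graphml_round_trip_preserves_metrics(tmp_path):
    rng = np.random.default_rng(8)
    W = (rng.integers(1, 4, size=(6, 6)) * (rng.random((6, 6)) < 0.4)).astype(float)
    np.fill_diagonal(W, 0)
    g = graph_from_matrix(W)
    p = tmp_path / "net.graphml"
    write_graphml(g, p)
    back = read_graphml(p)
    assert set(back.nodes) == set(g.nodes)
    assert global_efficiency(back, "count") == pytest.approx(global_efficiency(g, "count"))
    a, b = betweenness(g, "count"), betweenness(back, "count")
    for i in g.nodes:
        assert b[i] == pytest.approx(a[i])


def test_small_graph_oracle_spot_checks():
    """Random small digraphs agree with the exhaustive path-enumeration oracle."""
    rng = np.random.default_rng(17)
    for _ in range(25):
        n = int(rng.integers(2, 6))
        W = (rng.integers(1, 4, size=(n, n)) * (rng.random((n, n)) < 0.5)).astype(float)
        np.fill_diagonal(W, 0)
        g = graph_from_matrix(W)
        assert global_efficiency(g, "count") == pytest.approx(
            brute_global_efficiency(W), abs=1e-9)
        bt, cl, cc = betweenness(g, "count"), closeness(g, "count"), local_clustering(g, "count")
        wb, wc, wcc = brute_betweenness(W), brute_closeness_wf(W), brute_clustering_fagiolo(W)
        for i in range(n):
            assert bt[i] == pytest.approx(wb[i], abs=1e-9)
            assert cl[i] == pytest.approx(wc[i], abs=1e-9)
            assert cc[i] == pytest.approx(wcc[i], abs=1e-9)
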