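"""Batch-graph construction vs an independent brute-force oracle."""

import numpy as np
import pytest

from fundusgcn.graphbuild import (
    build_graph,
    combined_distance,
    normalized_adjacency,
    pairwise_distances,
)


def brute_force_edges(z, beta, k, radius):
    """O(n^2) reference: mutual k-NN pairs within the radius + self-loops.

    Distances recomputed from first principles (independent of the
    implementation's vectorised path).
    """
    z = np.asarray(z, dtype=np.float64)
    n = len(z)
    d_sp = np.zeros((n, n))
    d_se = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d_sp[i, j] = np.sqrt(((z[i] - z[j]) ** 2).sum())
            ni, nj = np.linalg.norm(z[i]), np.linalg.norm(z[j])
            if ni == 0 or nj == 0:
                d_se[i, j] = 1.0
            else:
                cos = float(z[i] @ z[j] / (ni * nj))
                d_se[i, j] = 1.0 - min(1.0, max(-1.0, cos))

    def minmax(d):
        lo, hi = d.min(), d.max()
        return (d - lo) / (hi - lo) if hi > lo else np.zeros_like(d)

    if n > 1:
        d = beta * minmax(d_sp) + (1 - beta) * minmax(d_se)
    else:
        d = np.zeros((1, 1))
    kk = min(k, n - 1)
    top = {}
    for i in range(n):
        order = sorted((d[i, j], j) for j in range(n) if j != i)
        top[i] = {j for _, j in order[:kk]}
    edges = {(i, i) for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if j in top[i] and i in top[j] and d[i, j] <= radius:
                edges.add((i, j))
    return edges


class TestPairwiseDistances:
    def test_identical_vectors_have_zero_distance(self):
        z = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 0.0]])
        d_sp, d_se = pairwise_distances(z)
        assert d_sp[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d_se[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_single_point_degenerates(self):
        d_sp, d_se = pairwise_distances(np.ones((1, 4)))
        assert d_sp.shape == (1, 1) and d_sp[0, 0] == 0.0

    def test_matrices_are_normalised_symmetric_zero_diag(self, rng):
        z = rng.normal(size=(12, 6))
        for d in pairwise_distances(z):
            np.testing.assert_allclose(d, d.T)
            assert np.diagonal(d).max() == 0.0
            assert d.min() >= 0.0 and d.max() <= 1.0 + 1e-12

    def test_orthogonal_unit_vectors_maximise_cosine_distance(self):
        z = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1e-3]])
        _, d_se = pairwise_distances(z)
        assert d_se[0, 1] == pytest.approx(1.0)

    def test_nonfinite_features_rejected(self):
        z = np.array([[0.0, np.inf], [1.0, 2.0]])
        with pytest.raises(ValueError):
            pairwise_distances(z)


class TestCombinedDistance:
    def test_convex_combination(self):
        assert combined_distance(0.2, 0.4, 0.5) == pytest.approx(0.3)

    @pytest.mark.parametrize("beta,expect", [(1.0, 0.2), (0.0, 0.4)])
    def test_boundary_weights(self, beta, expect):
        assert combined_distance(0.2, 0.4, beta) == pytest.approx(expect)

    @pytest.mark.parametrize("beta", [-0.1, 1.5])
    def test_beta_outside_unit_interval_rejected(self, beta):
        with pytest.raises(ValueError):
            combined_distance(0.2, 0.4, beta)


class TestBuildGraph:
    def test_matches_brute_force_oracle_on_random_batches(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(2, 65))
            d = int(rng.integers(2, 33))
            z = rng.normal(size=(n, d))
            beta = float(rng.uniform())
            k = int(rng.integers(1, 8))
            radius = float(rng.uniform(0.0, 0.6))
            graph = build_graph(z, beta=beta, k=k, radius=radius)
            assert set(graph.edges) == brute_force_edges(z, beta, k, radius)

    def test_adjacency_is_symmetric_with_self_loops(self, rng):
        graph = build_graph(rng.normal(size=(20, 5)))
        a = graph.adjacency()
        np.testing.assert_array_equal(a, a.T)
        assert np.diagonal(a).min() == 1.0
        assert graph.degrees.min() >= 1

    @pytest.mark.parametrize("param", ["k", "radius"])
    def test_enlarging_k_or_radius_never_removes_edges(self, rng, param):
        z = rng.normal(size=(24, 4))
        small = build_graph(z, k=2, radius=0.15)
        if param == "k":
            big = build_graph(z, k=6, radius=0.15)
        else:
            big = build_graph(z, k=2, radius=0.5)
        assert set(small.edges) <= set(big.edges)

    def test_coincident_points_are_linked(self, rng):
        z = rng.normal(size=(6, 3))
        z[3] = z[1]  # duplicates: mutual nearest at distance 0 <= radius
        graph = build_graph(z, k=2, radius=0.1)
        assert graph.has_edge(1, 3)
        assert graph.edges[(1, 3)] == 0.0

    def test_k_clamped_when_exceeding_batch(self, rng):
        z = rng.normal(size=(3, 2))
        graph = build_graph(z, k=10, radius=1.0)
        # radius 1.0 keeps every mutual pair: complete graph + self-loops
        assert len(graph.edges) == 3 + 3

    def test_single_node_graph(self):
        graph = build_graph(np.ones((1, 4)))
        assert set(graph.edges) == {(0, 0)}
        assert graph.degrees.tolist() == [1]

    def test_negative_radius_rejected(self, rng):
        with pytest.raises(ValueError):
            build_graph(rng.normal(size=(4, 2)), radius=-0.1)

    def test_bad_k_rejected(self, rng):
        with pytest.raises(ValueError):
            build_graph(rng.normal(size=(4, 2)), k=0)


class TestNormalizedAdjacency:
    def test_entries_follow_degree_rule(self, rng):
        graph = build_graph(rng.normal(size=(15, 4)), k=3, radius=0.4)
        s = normalized_adjacency(graph)
        deg = graph.degrees
        for (i, j) in graph.edges:
            expect = 1.0 / np.sqrt(deg[i] * deg[j])
            assert s[i, j] == pytest.approx(expect)
            assert s[j, i] == pytest.approx(expect)
        off = ~graph.adjacency().astype(bool)
        assert np.all(s[off] == 0.0)

    def test_edgelist_dump_roundtrip(self, rng, tmp_path):
        graph = build_graph(rng.normal(size=(8, 3)))
        path = tmp_path / "edges.txt"
        graph.dump_edgelist(path)
        lines = path.read_text().splitlines()
        assert len(lines) == len(graph.edges)
        i, j, w = lines[0].split()
        assert graph.has_edge(int(i), int(j))


class TestWeightedAggregation:
    def test_affinity_scaling_and_self_loops(self, rng):
        graph = build_graph(rng.normal(size=(10, 4)), k=4, radius=0.9)
        s0 = normalized_adjacency(graph)
        s1 = normalized_adjacency(graph, weighted=True)
        deg = graph.degrees
        for (i, j), w in graph.edges.items():
            if i == j:
                assert s1[i, i] == pytest.approx(s0[i, i])
            else:
                expect = max(0.0, 1.0 - w) / np.sqrt(deg[i] * deg[j])
                assert s1[i, j] == pytest.approx(expect)
        np.testing.assert_allclose(s1, s1.T)
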