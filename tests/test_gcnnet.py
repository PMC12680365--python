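"""GCN layers vs the dense oracle, heads, and model plumbing."""

import numpy as np
import pytest

from fundusgcn import _nn
from fundusgcn.backbone import TinyConvBackbone, extract_features
from fundusgcn.gcnnet import (
    GCNParams,
    GraphDRModel,
    HeadsParams,
    classify,
    gcn_layer,
    quality_score,
    refine,
)
from fundusgcn.graphbuild import BatchGraph, build_graph, normalized_adjacency


def random_graph(rng, n):
    """Random undirected graph with self-loops, built directly (not via
    build_graph) so the layer oracle is independent of graph construction."""
    edges = {(i, i): 0.0 for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.3:
                edges[(i, j)] = float(rng.random())
    degrees = np.zeros(n, dtype=np.int64)
    for (i, j) in edges:
        degrees[i] += 1
        if j != i:
            degrees[j] += 1
    return BatchGraph(n=n, edges=edges, degrees=degrees, beta=0.5, k=4, radius=0.1)


def dense_oracle(h, graph, w, b):
    """sigma(S H W^T + b) with S_ij = 1/sqrt(deg i deg j) on edges."""
    n = graph.n
    s = np.zeros((n, n))
    for (i, j) in graph.edges:
        v = 1.0 / np.sqrt(graph.degrees[i] * graph.degrees[j])
        s[i, j] = v
        s[j, i] = v
    return np.maximum(s @ h @ w.T + b, 0.0)


class TestGcnLayer:
    def test_matches_dense_oracle_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(2, 20))
            d_in = int(rng.integers(1, 10))
            d_out = int(rng.integers(1, 10))
            graph = random_graph(rng, n)
            h = rng.normal(size=(n, d_in))
            w = rng.normal(size=(d_out, d_in))
            b = rng.normal(size=d_out)
            np.testing.assert_allclose(
                gcn_layer(h, graph, w, b), dense_oracle(h, graph, w, b), atol=1e-5
            )

    def test_isolated_node_identity(self):
        graph = BatchGraph(
            n=1, edges={(0, 0): 0.0}, degrees=np.array([1]), beta=0.5, k=4, radius=0.1
        )
        h = np.array([[0.3, 1.2]])
        out = gcn_layer(h, graph, np.eye(2), np.zeros(2))
        np.testing.assert_allclose(out, h)

    def test_two_node_average(self):
        edges = {(0, 0): 0.0, (1, 1): 0.0, (0, 1): 0.5}
        graph = BatchGraph(
            n=2, edges=edges, degrees=np.array([2, 2]), beta=0.5, k=4, radius=0.1
        )
        h = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = gcn_layer(h, graph, np.eye(2), np.zeros(2))
        np.testing.assert_allclose(out, np.full((2, 2), 0.5))

    def test_dimension_mismatch_rejected(self, rng):
        graph = random_graph(rng, 4)
        with pytest.raises(ValueError):
            gcn_layer(rng.normal(size=(4, 3)), graph, rng.normal(size=(2, 5)), np.zeros(2))


class TestRefine:
    def test_deterministic_without_dropout(self, rng):
        graph = random_graph(rng, 8)
        params = GCNParams.init(6, (10, 5), rng=np.random.default_rng(1))
        z = rng.normal(size=(8, 6))
        np.testing.assert_array_equal(
            refine(z, graph, params), refine(z, graph, params)
        )

    def test_zero_layers_rejected(self):
        with pytest.raises(ValueError):
            GCNParams(weights=[], biases=[])

    def test_edgeless_graph_equals_per_node_mlp(self, rng):
        """Self-loops only: refinement must act sample-wise."""
        n = 6
        graph = BatchGraph(
            n=n,
            edges={(i, i): 0.0 for i in range(n)},
            degrees=np.ones(n, dtype=np.int64),
            beta=0.5, k=4, radius=0.1,
        )
        params = GCNParams.init(4, (7, 3), rng=np.random.default_rng(2))
        z = rng.normal(size=(n, 4))
        full = refine(z, graph, params)
        for i in range(n):
            sub = BatchGraph(
                n=1, edges={(0, 0): 0.0}, degrees=np.ones(1, dtype=np.int64),
                beta=0.5, k=4, radius=0.1,
            )
            single = refine(z[i : i + 1], sub, params)
            np.testing.assert_allclose(full[i], single[0], atol=1e-12)

    def test_node_permutation_equivariance(self, rng):
        z = rng.normal(size=(10, 5))
        graph = build_graph(z, k=3, radius=0.5)
        params = GCNParams.init(5, (8, 4), rng=np.random.default_rng(3))
        h = refine(z, graph, params)
        perm = rng.permutation(10)
        graph_p = build_graph(z[perm], k=3, radius=0.5)
        h_p = refine(z[perm], graph_p, params)
        np.testing.assert_allclose(h_p, h[perm], atol=1e-10)


class TestHeads:
    def test_zero_parameters_give_uniform_probabilities(self):
        heads = HeadsParams.init(8)
        probs = classify(np.random.default_rng(0).normal(size=(4, 8)), heads)
        np.testing.assert_allclose(probs, 0.2, atol=1e-12)

    def test_dominant_bias_wins_argmax(self, rng):
        heads = HeadsParams.init(8)
        heads.b_cls[2] = 10.0
        probs = classify(rng.normal(size=(6, 8)), heads)
        assert (probs.argmax(axis=1) == 2).all()

    def test_rows_sum_to_one(self, rng):
        heads = HeadsParams.init(8)
        heads.w_cls[...] = rng.normal(size=heads.w_cls.shape)
        probs = classify(rng.normal(size=(9, 8)), heads)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_quality_score_is_logistic(self, rng):
        heads = HeadsParams.init(8)
        q = quality_score(rng.normal(size=(5, 8)), heads)
        np.testing.assert_allclose(q, 0.5)  # zero weights -> logistic(0)
        heads.b_qa[0] = 20.0
        q_hi = quality_score(rng.normal(size=(5, 8)), heads)
        assert (q_hi > 0.999).all() and (q_hi < 1.0).all()


class TestBackbone:
    def test_gap_equals_explicit_spatial_mean(self, rng):
        bb = TinyConvBackbone(rng=np.random.default_rng(0))
        imgs = rng.random((3, 32, 32, 3))
        z, maps = extract_features(imgs, bb)
        manual = np.stack([
            [maps[i, c].mean() for c in range(maps.shape[1])]
            for i in range(maps.shape[0])
        ])
        np.testing.assert_allclose(z, manual, atol=1e-6)

    def test_batch_order_permutes_outputs(self, rng):
        bb = TinyConvBackbone(rng=np.random.default_rng(0))
        imgs = rng.random((5, 32, 32, 3))
        z, _ = extract_features(imgs, bb)
        z_rev, _ = extract_features(imgs[::-1], bb)
        np.testing.assert_allclose(z_rev, z[::-1])

    def test_constant_map_pools_to_constant(self):
        bb = TinyConvBackbone(init="he", rng=np.random.default_rng(0))
        for k in bb.params:
            bb.params[k][...] = 0.0
        bb.params["conv3.b"][...] = 0.7
        z, maps = extract_features(np.zeros((1, 32, 32, 3)), bb)
        np.testing.assert_allclose(z, 0.7, atol=1e-12)

    def test_shape_contract(self, rng):
        bb = TinyConvBackbone(rng=np.random.default_rng(0))
        z, maps = extract_features(rng.random((4, 64, 64, 3)), bb)
        assert z.shape == (4, bb.output_dim)
        assert maps.shape[:2] == (4, bb.output_dim)


class TestModelGradients:
    def test_full_backward_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        m = GraphDRModel(rng=rng)
        imgs = rng.random((5, 32, 32, 3))
        labels = rng.integers(0, 5, 5)

        def loss():
            res = m.forward(imgs)
            l, _, dl = _nn.softmax_cross_entropy(res.logits, labels)
            return l, res, dl

        base, res, dlogits = loss()
        grads = m.backward(res, dlogits)
        eps = 1e-6
        for key in ("backbone/conv0.w", "gcn/w0", "gcn/w1", "heads/b_cls"):
            p = m.params[key]
            for fi in (0, p.size // 2):
                orig = p.flat[fi]
                p.flat[fi] = orig + eps
                lp, _, _ = loss()
                p.flat[fi] = orig - eps
                lm, _, _ = loss()
                p.flat[fi] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[key].flat[fi]
                assert abs(num - ana) <= 1e-4 * max(1.0, abs(num))


class TestCheckpoint:
    def test_save_load_roundtrip_preserves_forward(self, tmp_path, rng):
        m = GraphDRModel(rng=np.random.default_rng(5))
        imgs = rng.random((4, 32, 32, 3))
        m.calibrate(imgs)
        before = m.forward(imgs).probs
        path = tmp_path / "ckpt.npz"
        m.save(path)
        m2 = GraphDRModel.load(path)
        np.testing.assert_allclose(m2.forward(imgs).probs, before, atol=1e-12)

    def test_missing_checkpoint_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            GraphDRModel.load(tmp_path / "nope.npz")
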