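import numpy as np
import pytest

from gowmpn import (
    GOWConfig,
    GraphStructureError,
    LabelSchema,
    ModelConfig,
    build_document_graph,
    build_edge_registry,
    count_parameters,
    forward,
    init_parameters,
    message_dense,
    message_max,
    message_sparse,
    node_update,
    readout,
)
from gowmpn.gow import DocumentGraph
from gowmpn.preprocess import EncodedDocument, Vocabulary

from conftest import random_graph_instance


def random_params(vocab, registry, schema, w, seed=0, use_eta=False):
    config = ModelConfig(embedding_dim=w, use_eta=use_eta)
    rng = np.random.default_rng(seed)
    params = init_parameters(vocab, registry, schema, config, rng)
    # spread edge weights away from 1 so aggregation differences are visible
    params.edge_weights[:] = rng.normal(0.0, 1.0, size=params.edge_weights.shape)
    return params


def nested_loop_max(graph, params):
    """Per-node, per-dimension brute-force realization of the max rule."""
    w = params.embedding.shape[1]
    M = np.empty((graph.n_nodes, w))
    for n in range(graph.n_nodes):
        incoming = [e for e in range(graph.n_edges) if graph.dst[e] == n]
        assert incoming, "every node must have an incoming edge"
        for k in range(w):
            M[n, k] = max(
                params.edge_weights[graph.edge_ids[e]]
                * params.embedding[graph.node_words[graph.src[e]], k]
                for e in incoming)
    return M


def nested_loop_sum(graph, params):
    w = params.embedding.shape[1]
    M = np.zeros((graph.n_nodes, w))
    for e in range(graph.n_edges):
        M[graph.dst[e]] += (params.edge_weights[graph.edge_ids[e]]
                            * params.embedding[graph.node_words[graph.src[e]]])
    return M


@pytest.fixture()
def toy_schema():
    return LabelSchema(tasks=("t",), classes={"t": ("a", "b")})


class TestMessageMax:
    def test_single_node_self_weight_one_returns_embedding(self, toy_schema):
        vocab = Vocabulary.from_words(["x"])
        doc = EncodedDocument("d", np.array([2]), {})
        reg = build_edge_registry([doc], GOWConfig(window=1), vocab.size)
        params = random_params(vocab, reg, toy_schema, w=4, seed=1)
        params.edge_weights[:] = 1.0
        M = message_max(build_document_graph(doc, reg, GOWConfig(window=1)), params)
        np.testing.assert_allclose(M, params.embedding[[2]])

    def test_dimensionwise_max_over_neighbor_and_zero_self_edge(self, toy_schema):
        # node 1 receives from node 0 with weight 2 and from itself with weight 0
        graph = DocumentGraph(node_words=np.array([2, 3]),
                              src=np.array([0, 0, 1]),
                              dst=np.array([0, 1, 1]),
                              edge_ids=np.array([1, 2, 3]))
        vocab = Vocabulary.from_words(["a", "n"])
        reg = build_edge_registry([EncodedDocument("d", np.array([2, 3]), {})],
                                  GOWConfig(window=1), vocab.size)
        params = random_params(vocab, reg, toy_schema, w=2, seed=2)
        params.embedding[2] = [1.0, -1.0]
        params.edge_weights[:] = 0.0
        params.edge_weights[2] = 2.0
        # self edge on node 1 has weight 0 => max over {2*r_a, 0*r_n} per dim
        M = message_max(graph, params)
        np.testing.assert_allclose(M[1], [2.0, 0.0])

    def test_matches_nested_loop_oracle(self, toy_schema):
        rng = np.random.default_rng(4)
        for _ in range(15):
            vocab, doc, config, reg, graph = random_graph_instance(rng, max_nodes=8)
            params = random_params(vocab, reg, toy_schema, w=5,
                                   seed=int(rng.integers(1000)))
            np.testing.assert_allclose(message_max(graph, params),
                                       nested_loop_max(graph, params))

    def test_isolated_node_raises(self, toy_schema):
        graph = DocumentGraph(node_words=np.array([2, 3]),
                              src=np.array([0]), dst=np.array([0]),
                              edge_ids=np.array([1]))
        vocab = Vocabulary.from_words(["a", "n"])
        reg = build_edge_registry([EncodedDocument("d", np.array([2, 3]), {})],
                                  GOWConfig(window=1), vocab.size)
        params = random_params(vocab, reg, toy_schema, w=2)
        with pytest.raises(GraphStructureError):
            message_max(graph, params)


class TestSumMessages:
    def test_zero_weights_annihilate(self, toy_schema):
        rng = np.random.default_rng(5)
        vocab, doc, config, reg, graph = random_graph_instance(rng)
        params = random_params(vocab, reg, toy_schema, w=3)
        params.edge_weights[:] = 0.0
        np.testing.assert_array_equal(message_dense(graph, params), 0.0)

    def test_single_node_self_weight_one_is_identity(self, toy_schema):
        vocab = Vocabulary.from_words(["x"])
        doc = EncodedDocument("d", np.array([2]), {})
        reg = build_edge_registry([doc], GOWConfig(window=1), vocab.size)
        params = random_params(vocab, reg, toy_schema, w=4, seed=3)
        params.edge_weights[:] = 1.0
        graph = build_document_graph(doc, reg, GOWConfig(window=1))
        np.testing.assert_allclose(message_dense(graph, params),
                                   params.embedding[[2]])
        np.testing.assert_allclose(message_sparse(graph, params),
                                   params.embedding[[2]])

    def test_sparse_equals_dense_on_random_graphs(self, toy_schema):
        """The gather/scatter path must reproduce the adjacency product."""
        rng = np.random.default_rng(6)
        worst = 0.0
        for _ in range(100):
            vocab, doc, config, reg, graph = random_graph_instance(
                rng, max_nodes=50, max_vocab=16)
            w = int(rng.integers(1, 17))
            params = random_params(vocab, reg, toy_schema, w=w,
                                   seed=int(rng.integers(10000)))
            dev = np.max(np.abs(message_sparse(graph, params)
                                - message_dense(graph, params)))
            worst = max(worst, dev)
        assert worst < 1e-5

    def test_sum_modes_match_explicit_neighbor_sum(self, toy_schema):
        rng = np.random.default_rng(7)
        vocab, doc, config, reg, graph = random_graph_instance(rng, max_nodes=12)
        params = random_params(vocab, reg, toy_schema, w=4, seed=8)
        oracle = nested_loop_sum(graph, params)
        np.testing.assert_allclose(message_sparse(graph, params), oracle)
        np.testing.assert_allclose(message_dense(graph, params), oracle)


class TestNodeUpdate:
    def test_eta_one_limit_keeps_old_state(self):
        rng = np.random.default_rng(9)
        M, r_old = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        eta = np.full(4, 1.0 - 1e-12)
        np.testing.assert_allclose(node_update(M, r_old, eta, True), r_old,
                                   atol=1e-10)

    def test_fixed_point_when_message_equals_state(self):
        rng = np.random.default_rng(10)
        r = rng.normal(size=(5, 2))
        out = node_update(r.copy(), r, np.full(5, 0.5), True)
        np.testing.assert_allclose(out, r)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(11)
        M, r_old = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
        eta = rng.uniform(0.01, 0.99, size=6)
        out = node_update(M, r_old, eta, True)
        lo = np.minimum(M, r_old) - 1e-12
        hi = np.maximum(M, r_old) + 1e-12
        assert np.all(out >= lo) and np.all(out <= hi)

    def test_disabled_eta_passes_message_through(self):
        rng = np.random.default_rng(12)
        M, r_old = rng.normal(size=(3, 2)), rng.normal(size=(3, 2))
        np.testing.assert_array_equal(node_update(M, r_old, None, False), M)


class TestReadout:
    @pytest.fixture()
    def setup(self, tiny_schema):
        vocab = Vocabulary.from_words([f"w{i}" for i in range(5)])
        doc = EncodedDocument("d", np.array([2, 3, 4, 5, 6]), {})
        reg = build_edge_registry([doc], GOWConfig(window=2), vocab.size)
        params = random_params(vocab, reg, tiny_schema, w=6, seed=13)
        rng = np.random.default_rng(14)
        H = rng.normal(size=(5, 6))
        return params, H

    def test_distributions_normalize(self, setup):
        params, H = setup
        out = readout(H, params)
        for task, y in out.items():
            assert y.shape == (params.schema.n_classes(task),)
            assert abs(y.sum() - 1.0) < 1e-6
            assert np.all(y >= 0)

    def test_permutation_invariance(self, setup):
        params, H = setup
        perm = np.random.default_rng(15).permutation(H.shape[0])
        out1 = readout(H, params)
        out2 = readout(H[perm], params)
        for task in out1:
            np.testing.assert_allclose(out1[task], out2[task])

    def test_zero_head_gives_uniform(self, setup):
        params, H = setup
        for task in params.schema.tasks:
            V, b = params.heads[task]
            V[:] = 0.0
            b[:] = 0.0
        out = readout(H, params)
        for task, y in out.items():
            np.testing.assert_allclose(y, 1.0 / len(y))

    def test_empty_document_rejected(self, setup):
        params, H = setup
        with pytest.raises(GraphStructureError):
            readout(H, params, real_mask=np.zeros(H.shape[0], dtype=bool))


class TestForward:
    def test_dense_and_sparse_give_identical_distributions(self, toy_schema):
        rng = np.random.default_rng(16)
        for _ in range(10):
            vocab, doc, config, reg, graph = random_graph_instance(rng, max_nodes=20)
            params = random_params(vocab, reg, toy_schema, w=8,
                                   seed=int(rng.integers(1000)))
            y_dense = forward(doc, graph, params,
                              ModelConfig(embedding_dim=8, aggregation="dense_sum"))
            y_sparse = forward(doc, graph, params,
                               ModelConfig(embedding_dim=8, aggregation="sparse_sum"))
            for task in y_dense:
                np.testing.assert_allclose(y_dense[task], y_sparse[task], atol=1e-5)

    def test_forward_is_deterministic(self, toy_schema):
        rng = np.random.default_rng(17)
        vocab, doc, config, reg, graph = random_graph_instance(rng)
        params = random_params(vocab, reg, toy_schema, w=4, seed=18)
        config = ModelConfig(embedding_dim=4)
        y1 = forward(doc, graph, params, config)
        y2 = forward(doc, graph, params, config)
        for task in y1:
            np.testing.assert_array_equal(y1[task], y2[task])

    def test_single_token_document_reduces_to_self_message(self, toy_schema):
        vocab = Vocabulary.from_words(["x"])
        doc = EncodedDocument("d", np.array([2]), {})
        config = GOWConfig(window=1)
        reg = build_edge_registry([doc], config, vocab.size)
        graph = build_document_graph(doc, reg, config)
        params = random_params(vocab, reg, toy_schema, w=4, seed=19)
        mconfig = ModelConfig(embedding_dim=4, activation="identity")
        y = forward(doc, graph, params, mconfig)
        e_self = params.edge_weights[reg.pair_to_edge_id[(2, 2)]]
        pooled = e_self * params.embedding[2]
        V, b = params.heads["t"]
        expected = np.exp(V @ pooled + b)
        expected /= expected.sum()
        np.testing.assert_allclose(y["t"], expected)


class TestCountParameters:
    def test_paper_scale_embedding_block(self):
        schema = LabelSchema(tasks=("t",), classes={"t": ("a", "b")})
        counts = count_parameters(202373, None, schema,
                                  ModelConfig(embedding_dim=300))
        assert counts["embedding"] == 60_711_900

    def test_hand_count_tiny_model(self):
        schema = LabelSchema(tasks=("t",), classes={"t": ("a", "b")})
        counts = count_parameters(2, None, schema, ModelConfig(embedding_dim=1))
        assert counts == {"embedding": 2, "edges": 0, "eta": 0, "heads": 4,
                          "total": 6}

    def test_matches_direct_enumeration_of_trainable_entries(self, tiny_schema):
        vocab = Vocabulary.from_words([f"w{i}" for i in range(7)])
        docs = [EncodedDocument("d", np.arange(2, 9), {})]
        config = GOWConfig(window=2)
        reg = build_edge_registry(docs, config, vocab.size)
        mconfig = ModelConfig(embedding_dim=5, use_eta=True)
        params = init_parameters(vocab, reg, tiny_schema, mconfig,
                                 np.random.default_rng(20))
        enumerated = (params.embedding.size + params.edge_weights.size
                      + params.eta_raw.size
                      + sum(V.size + b.size for V, b in params.heads.values()))
        counts = count_parameters(vocab, reg, tiny_schema, mconfig)
        assert counts["total"] == enumerated

    def test_sentinel_exclusion(self):
        schema = LabelSchema(tasks=("t",), classes={"t": ("a", "b")})
        vocab = Vocabulary.from_words(["x", "y", "z"])
        counts = count_parameters(vocab, None, schema, ModelConfig(embedding_dim=2),
                                  include_sentinels=False)
        assert counts["embedding"] == 3 * 2
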