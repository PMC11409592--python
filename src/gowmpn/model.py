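"""The message-passing graph-of-words classifier.

Every node n of a document graph aggregates messages from its neighbors a,
each message being the neighbor's embedding r_a scaled by the globally shared
trainable edge weight e_an.  Three aggregation modes are provided:

``max``
    The reference text-level GCN rule: M_n[k] = max_a e_an * r_a[k],
    dimension-wise, followed by the retention update
    r_new = (1 - eta_n) * M_n + eta_n * r_old with a per-node trainable
    retention coefficient eta_n squashed into (0, 1).

``dense_sum``
    M'_n = sum_i e_in * r_i realized as a full adjacency-matrix product, with
    e_in = 0 for non-adjacent pairs.  Quadratic in document length; kept as
    the transparent testing oracle for the sparse path.

``sparse_sum``
    The same weighted sum computed by gathering the edge-indexed embedding
    rows and weights into flat arrays and scatter-summing by target node.
    Mathematically identical to ``dense_sum`` (up to summation-order
    rounding); linear in the number of edges, and the default.

After ``n_layers`` rounds of aggregation + update, the document vector is the
sum of the node states over real (non-PAD) nodes, and each task head maps it
through y_t = softmax(sigma(V_t @ pooled + b_t)).

The model is small and regular enough that the forward pass and the exact
backward pass (see :mod:`gowmpn.train`) are written directly in numpy/scipy;
all arithmetic is float64.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus_io import LabelSchema
from .errors import ConfigError, GraphStructureError
from .gow import DocumentGraph, EdgeRegistry
from .preprocess import EncodedDocument, PAD_INDEX, Vocabulary

AGGREGATION_MODES = ("max", "dense_sum", "sparse_sum")
ACTIVATIONS = ("relu", "identity", "tanh")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``embedding_dim`` is the node-embedding length w (default 300).
    ``aggregation`` selects the message rule above.  ``use_eta`` enables the
    reference retention update; with the sum rules the registered self edge
    already plays that role, so it defaults off.  ``activation`` is the
    elementwise nonlinearity applied before the softmax.  ``dropout`` is
    applied to the pooled document vector at training time.
    """

    embedding_dim: int = 300
    aggregation: str = "sparse_sum"
    n_layers: int = 1
    use_eta: bool = False
    activation: str = "relu"
    dropout: float = 0.0

    def __post_init__(self):
        if self.embedding_dim < 1:
            raise ConfigError("embedding_dim must be >= 1")
        if self.aggregation not in AGGREGATION_MODES:
            raise ConfigError(f"aggregation must be one of {AGGREGATION_MODES}")
        if self.activation not in ACTIVATIONS:
            raise ConfigError(f"activation must be one of {ACTIVATIONS}")
        if self.n_layers < 1:
            raise ConfigError("n_layers must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must lie in [0, 1)")


def activation_fn(name: str):
    if name == "relu":
        return lambda z: np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh
    return lambda z: z


def activation_grad(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (z > 0).astype(float)
    if name == "tanh":
        return 1.0 - a * a
    return np.ones_like(z)


@dataclass
class ModelParameters:
    """All trainable tables, plus the structures that give them meaning."""

    vocabulary: Vocabulary
    registry: EdgeRegistry
    schema: LabelSchema
    embedding: np.ndarray                    # (N, w); PAD row frozen at zero
    edge_weights: np.ndarray                 # (E_count,)
    heads: dict[str, tuple[np.ndarray, np.ndarray]]  # task -> (V (C, w), b (C,))
    eta_raw: np.ndarray | None = None        # (N,), squashed by sigmoid when used

    def __post_init__(self):
        if self.embedding.shape[0] != self.vocabulary.size:
            raise ConfigError("embedding row count does not match vocabulary size")
        if self.edge_weights.shape != (self.registry.E_count,):
            raise ConfigError("edge-weight table does not match registry size")
        for task in self.schema.tasks:
            V, b = self.heads[task]
            C = self.schema.n_classes(task)
            if V.shape != (C, self.embedding.shape[1]) or b.shape != (C,):
                raise ConfigError(f"head shapes for task {task!r} are inconsistent")

    @property
    def eta(self) -> np.ndarray | None:
        """Retention coefficients in (0, 1)."""
        if self.eta_raw is None:
            return None
        return 1.0 / (1.0 + np.exp(-self.eta_raw))

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            vocabulary=self.vocabulary,
            registry=self.registry,
            schema=self.schema,
            embedding=self.embedding.copy(),
            edge_weights=self.edge_weights.copy(),
            eta_raw=None if self.eta_raw is None else self.eta_raw.copy(),
            heads={t: (V.copy(), b.copy()) for t, (V, b) in self.heads.items()},
        )


def init_parameters(
    vocab: Vocabulary,
    registry: EdgeRegistry,
    schema: LabelSchema,
    config: ModelConfig,
    rng: np.random.Generator,
) -> ModelParameters:
    """Initialize all tables.

    Embedding rows ~ N(0, 1/w) (PAD frozen at zero); edge weights 1 + small
    noise so the initial aggregation is close to a plain neighborhood sum;
    heads have small random V and zero bias; eta_raw starts at 0 (eta = 0.5).
    """
    w = config.embedding_dim
    N = vocab.size
    embedding = rng.normal(0.0, 1.0 / np.sqrt(w), size=(N, w))
    embedding[PAD_INDEX] = 0.0
    edge_weights = 1.0 + rng.normal(0.0, 0.01, size=registry.E_count)
    heads = {}
    for task in schema.tasks:
        C = schema.n_classes(task)
        heads[task] = (rng.normal(0.0, 0.1, size=(C, w)), np.zeros(C))
    eta_raw = np.zeros(N) if config.use_eta else None
    return ModelParameters(
        vocabulary=vocab, registry=registry, schema=schema,
        embedding=embedding, edge_weights=edge_weights,
        heads=heads, eta_raw=eta_raw,
    )


# ---------------------------------------------------------------------------
# message aggregation over node states H (one row per node)

def _aggregate_sparse(H, graph: DocumentGraph, edge_weights):
    M = np.zeros_like(H)
    contrib = edge_weights[graph.edge_ids][:, None] * H[graph.src]
    np.add.at(M, graph.dst, contrib)
    return M


def _aggregate_dense(H, graph: DocumentGraph, edge_weights):
    n = graph.n_nodes
    A = np.zeros((n, n))
    A[graph.dst, graph.src] = edge_weights[graph.edge_ids]
    return A @ H


def _aggregate_max(H, graph: DocumentGraph, edge_weights):
    indeg = np.bincount(graph.dst, minlength=graph.n_nodes)
    if np.any(indeg == 0):
        raise GraphStructureError(
            "max aggregation requires every node to have an incoming edge "
            "(enable self-loops)")
    M = np.full_like(H, -np.inf)
    contrib = edge_weights[graph.edge_ids][:, None] * H[graph.src]
    np.maximum.at(M, graph.dst, contrib)
    return M


def message_max(graph: DocumentGraph, params: ModelParameters) -> np.ndarray:
    """Dimension-wise maximum of the weighted neighbor embeddings."""
    return _aggregate_max(params.embedding[graph.node_words], graph, params.edge_weights)


def message_dense(graph: DocumentGraph, params: ModelParameters) -> np.ndarray:
    """Weighted sum via an explicit full adjacency-matrix product."""
    return _aggregate_dense(params.embedding[graph.node_words], graph, params.edge_weights)


def message_sparse(graph: DocumentGraph, params: ModelParameters) -> np.ndarray:
    """Weighted sum via gather (edge-indexed rows) and scatter-sum by target."""
    return _aggregate_sparse(params.embedding[graph.node_words], graph, params.edge_weights)


def aggregate(H, graph, edge_weights, mode: str):
    if mode == "max":
        return _aggregate_max(H, graph, edge_weights)
    if mode == "dense_sum":
        return _aggregate_dense(H, graph, edge_weights)
    return _aggregate_sparse(H, graph, edge_weights)


def node_update(
    M: np.ndarray,
    r_old: np.ndarray,
    eta: np.ndarray | None,
    use_eta: bool,
) -> np.ndarray:
    """r_new = (1 - eta) * M + eta * r_old, or plainly M when eta is disabled.

    With eta in (0, 1) each component of r_new is a convex combination of the
    message and the previous state.
    """
    if not use_eta:
        return M
    if eta is None:
        raise ConfigError("use_eta requested but parameters carry no eta table")
    eta_col = eta[:, None]
    return (1.0 - eta_col) * M + eta_col * r_old


def readout(
    H: np.ndarray,
    params: ModelParameters,
    activation: str = "relu",
    real_mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Sum-pool node states and apply each task's softmax head.

    The pooled vector is the sum over real (non-PAD) nodes, so the result is
    invariant to node-order permutations.
    """
    if real_mask is not None:
        if not np.any(real_mask):
            raise GraphStructureError("readout over a document with no real nodes")
        pooled = H[real_mask].sum(axis=0)
    else:
        if H.shape[0] == 0:
            raise GraphStructureError("readout over an empty document")
        pooled = H.sum(axis=0)
    act = activation_fn(activation)
    out = {}
    for task in params.schema.tasks:
        V, b = params.heads[task]
        a = act(V @ pooled + b)
        out[task] = softmax(a)
    return out


def softmax(a: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = a - np.max(a, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def forward(
    doc: EncodedDocument,
    graph: DocumentGraph,
    params: ModelParameters,
    config: ModelConfig,
) -> dict[str, np.ndarray]:
    """Full single-document forward pass (inference: dropout disabled)."""
    H = params.embedding[graph.node_words]
    eta = params.eta
    for _ in range(config.n_layers):
        M = aggregate(H, graph, params.edge_weights, config.aggregation)
        eta_nodes = None if eta is None else eta[graph.node_words]
        H = node_update(M, H, eta_nodes, config.use_eta)
    return readout(H, params, activation=config.activation)


def count_parameters(
    vocab: Vocabulary | int,
    registry: EdgeRegistry | None,
    schema: LabelSchema,
    config: ModelConfig,
    include_sentinels: bool = True,
) -> dict[str, int]:
    """Trainable-parameter breakdown: embedding, edges, eta, heads, total.

    ``vocab`` may be a plain integer N (a word-type count) for capacity
    planning without materializing a vocabulary.  ``include_sentinels=False``
    excludes the PAD and UNK rows from the embedding (and eta) accounting.
    """
    N = vocab if isinstance(vocab, int) else vocab.size
    n_rows = N if include_sentinels else max(N - 2, 0)
    w = config.embedding_dim
    embedding = n_rows * w
    edges = registry.E_count if registry is not None else 0
    eta = n_rows if config.use_eta else 0
    heads = sum(schema.n_classes(t) * w + schema.n_classes(t) for t in schema.tasks)
    return {
        "embedding": embedding,
        "edges": edges,
        "eta": eta,
        "heads": heads,
        "total": embedding + edges + eta + heads,
    }
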