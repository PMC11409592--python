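"""Graph-of-words construction.

A document is represented as a graph with one node per *token position* and a
directed edge between every ordered pair of positions at token distance at
most ``window`` (plus a self edge on every node).  Edge weights are not stored
per document: each edge carries the identifier of a *globally shared* trainable
scalar, keyed by the ordered pair of word types it connects.  Pairs never seen
while building the registry fall back to a single reserved "public" weight, so
a trained model can score documents containing unseen word combinations — the
property that makes the model deployable to new registries.

Because edge weights are keyed by word pair regardless of position or
direction-in-text, the representation is insensitive to word inversion: for a
window of 1, "poorly differentiated" and "differentiated poorly" induce the
same unordered word-pair set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError
from .preprocess import EncodedDocument, PAD_INDEX

PUBLIC_EDGE_ID = 0


@dataclass(frozen=True)
class GOWConfig:
    """Co-occurrence window and registry pruning.

    ``window`` is the maximum token distance d defining co-occurrence; the
    neighborhood used at message time is the same d (the two notions are one
    windowing concept).  ``edge_min_count`` prunes word pairs rarer than the
    threshold from the registry (they fall back to the public weight).
    """

    window: int = 10
    edge_min_count: int = 1
    self_loops: bool = True

    def __post_init__(self):
        if self.window < 1:
            raise ConfigError("window must be >= 1")
        if self.edge_min_count < 1:
            raise ConfigError("edge_min_count must be >= 1")


@dataclass
class EdgeRegistry:
    """Dense mapping from ordered word-index pairs to edge-weight identifiers.

    Identifier 0 is the public fallback; registered pairs occupy 1..E_count-1
    in sorted pair order, which makes identifier assignment deterministic.
    """

    pair_to_edge_id: dict[tuple[int, int], int]
    self_loops: bool = True
    # sorted pair codes for vectorized lookup, built lazily
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)
    _code_ids: np.ndarray | None = field(default=None, repr=False, compare=False)
    _code_base: int = field(default=0, repr=False, compare=False)

    @property
    def public_edge_id(self) -> int:
        return PUBLIC_EDGE_ID

    @property
    def E_count(self) -> int:
        """Number of trainable edge weights: registered pairs + the public one."""
        return len(self.pair_to_edge_id) + 1

    def edge_id(self, a: int, n: int) -> int:
        return self.pair_to_edge_id.get((a, n), PUBLIC_EDGE_ID)

    def _ensure_lookup(self) -> None:
        if self._codes is not None:
            return
        base = 1 + max((max(a, n) for a, n in self.pair_to_edge_id), default=0)
        pairs = np.array(sorted(self.pair_to_edge_id), dtype=np.int64).reshape(-1, 2)
        codes = pairs[:, 0] * base + pairs[:, 1]
        ids = np.array([self.pair_to_edge_id[(int(a), int(n))] for a, n in pairs], dtype=np.int64)
        object.__setattr__(self, "_codes", codes)
        object.__setattr__(self, "_code_ids", ids)
        object.__setattr__(self, "_code_base", base)

    def edge_ids(self, src_words: np.ndarray, dst_words: np.ndarray) -> np.ndarray:
        """Vectorized ``edge_id`` over parallel word-index arrays."""
        self._ensure_lookup()
        if len(self._codes) == 0:
            return np.full(len(src_words), PUBLIC_EDGE_ID, dtype=np.int64)
        base = self._code_base
        out_of_range = (src_words >= base) | (dst_words >= base)
        codes = np.where(out_of_range, -1, src_words * base + dst_words)
        pos = np.searchsorted(self._codes, codes)
        pos = np.clip(pos, 0, len(self._codes) - 1)
        hit = (self._codes[pos] == codes) & ~out_of_range
        return np.where(hit, self._code_ids[pos], PUBLIC_EDGE_ID)

    def to_tsv(self, path, vocab) -> None:
        """Inspection dump: word_a, word_b, edge_id (public row word '*')."""
        import csv

        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["word_a", "word_b", "edge_id"])
            writer.writerow(["*", "*", PUBLIC_EDGE_ID])
            for (a, n), eid in sorted(self.pair_to_edge_id.items()):
                writer.writerow([vocab.word(a), vocab.word(n), eid])


@dataclass
class DocumentGraph:
    """Per-document message-passing graph over token positions."""

    node_words: np.ndarray  # word index per node position
    src: np.ndarray         # edge source node positions
    dst: np.ndarray         # edge target node positions
    edge_ids: np.ndarray    # shared-weight identifier per edge

    @property
    def n_nodes(self) -> int:
        return len(self.node_words)

    @property
    def n_edges(self) -> int:
        return len(self.src)


def _windowed_pairs(tokens: np.ndarray, window: int):
    """All ordered position pairs (i, j) with 0 < |i - j| <= window."""
    srcs, dsts = [], []
    n = len(tokens)
    for k in range(1, min(window, n - 1) + 1):
        idx = np.arange(n - k)
        srcs.append(idx)
        dsts.append(idx + k)
        srcs.append(idx + k)
        dsts.append(idx)
    if not srcs:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(srcs), np.concatenate(dsts)


def build_edge_registry(
    corpus: Iterable[EncodedDocument],
    config: GOWConfig,
    vocab_size: int,
) -> EdgeRegistry:
    """Register a shared weight for every windowed ordered word pair.

    A pair (a, n) is registered when words a and n co-occur (a at position i,
    n at position j, 0 < |i-j| <= window) at least ``edge_min_count`` times in
    the corpus.  With self-loops enabled, a self pair (w, w) is registered for
    every non-PAD vocabulary word regardless of count — the self edge is how a
    node retains its own embedding through the weighted-sum aggregation.
    """
    codes: list[np.ndarray] = []
    n_docs = 0
    for doc in corpus:
        n_docs += 1
        toks = np.asarray(doc.token_indices, dtype=np.int64)
        s, d = _windowed_pairs(toks, config.window)
        if len(s):
            codes.append(toks[s] * vocab_size + toks[d])
    if n_docs == 0:
        raise ConfigError("cannot build an edge registry from an empty corpus")
    if codes:
        allc = np.concatenate(codes)
        uniq, counts = np.unique(allc, return_counts=True)
        uniq = uniq[counts >= config.edge_min_count]
    else:
        uniq = np.empty(0, dtype=np.int64)
    pairs = {(int(c // vocab_size), int(c % vocab_size)) for c in uniq}
    if config.self_loops:
        pairs.update((w, w) for w in range(1, vocab_size))  # every word incl. UNK, not PAD
    pair_to_edge_id = {p: i for i, p in enumerate(sorted(pairs), start=1)}
    return EdgeRegistry(pair_to_edge_id=pair_to_edge_id, self_loops=config.self_loops)


def build_document_graph(
    doc: EncodedDocument,
    registry: EdgeRegistry,
    config: GOWConfig,
) -> DocumentGraph:
    """One node per token position; windowed directed edges plus self edges.

    Edge identifiers are looked up by ordered word pair; unregistered pairs
    carry the public identifier.
    """
    toks = np.asarray(doc.token_indices, dtype=np.int64)
    if len(toks) == 0:
        raise ConfigError(f"document {doc.doc_id!r} has no tokens")
    src, dst = _windowed_pairs(toks, config.window)
    if config.self_loops:
        loops = np.arange(len(toks), dtype=np.int64)
        src = np.concatenate([src, loops])
        dst = np.concatenate([dst, loops])
    edge_ids = registry.edge_ids(toks[src], toks[dst])
    return DocumentGraph(node_words=toks, src=src, dst=dst, edge_ids=edge_ids)


def graph_stats(graph: DocumentGraph) -> tuple[int, int, int]:
    """(n_nodes, n_edges, n_public_edges)."""
    return (
        graph.n_nodes,
        graph.n_edges,
        int(np.count_nonzero(graph.edge_ids == PUBLIC_EDGE_ID)),
    )
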