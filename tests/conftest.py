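import numpy as np
import pytest

from gowmpn import (
    GeneratorConfig,
    GOWConfig,
    LabelSchema,
    build_document_graph,
    build_edge_registry,
    build_schema,
    build_vocabulary,
    encode_corpus,
    generate_corpus,
)
from gowmpn.preprocess import EncodedDocument, Vocabulary


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(n_documents=400, seed=11)

@pytest.fixture(scope="session")
def corpus(gen_config):
    return generate_corpus(gen_config)

@pytest.fixture(scope="session")
def schema(gen_config):
    return build_schema(gen_config)

@pytest.fixture(scope="session")
def records(corpus):
    return [c.record for c in corpus]

@pytest.fixture(scope="session")
def vocab(records):
    return build_vocabulary(records)

@pytest.fixture(scope="session")
def encoded(records, vocab, schema):
    return encode_corpus(records, vocab, schema)


@pytest.fixture(scope="session")
def tiny_schema():
    return LabelSchema(tasks=("grade", "side"),
                       classes={"grade": ("1", "2", "3"), "side": ("left", "right")})


def random_graph_instance(rng, max_nodes=50, max_vocab=12, window=None):
    """A random encoded document + registry + graph for oracle tests."""
    n_words = int(rng.integers(4, max_vocab))
    vocab = Vocabulary.from_words([f"w{i}" for i in range(n_words)])
    n_tokens = int(rng.integers(1, max_nodes + 1))
    toks = rng.integers(2, vocab.size, size=n_tokens)
    doc = EncodedDocument("rnd", toks, {})
    window = int(rng.integers(1, 4)) if window is None else window
    config = GOWConfig(window=window)
    registry = build_edge_registry([doc], config, vocab.size)
    graph = build_document_graph(doc, registry, config)
    return vocab, doc, config, registry, graph
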