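"""Tokenization, vocabulary construction and document encoding.

Tokenization is deliberately simple: lowercase, and every maximal run of
alphanumeric characters is a token (all punctuation, including hyphens, acts
as a separator).  Pathology-report phrasing varies mostly in separators and
ordering — "grade 3", "grade (g1-3): 3", "g3" — so splitting on punctuation
and keeping digit tokens preserves exactly the variation the downstream graph
representation is designed to absorb.

The vocabulary reserves index 0 for PAD and index 1 for UNK; real word types
occupy indices 2..N-1 ordered by descending corpus frequency, ties broken
lexicographically, which makes vocabulary construction deterministic.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import LabelSchema, RawRecord
from .errors import ConfigError, EmptyDocumentError

PAD_INDEX = 0
UNK_INDEX = 1
PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase alphanumeric tokenizer; deterministic, may return []."""
    return _TOKEN_RE.findall(text.lower())


@dataclass
class Vocabulary:
    """Bidirectional word↔index map with PAD/UNK sentinels at 0 and 1."""

    index_to_word: list[str]
    word_to_index: dict[str, int]
    counts: list[int]  # corpus frequency per index; 0 for sentinels

    @classmethod
    def from_words(cls, words: Sequence[str], counts: Sequence[int] | None = None) -> "Vocabulary":
        """Build from an ordered list of non-sentinel word types."""
        itos = [PAD_TOKEN, UNK_TOKEN, *words]
        if len(set(itos)) != len(itos):
            raise ConfigError("vocabulary contains duplicate words")
        stoi = {w: i for i, w in enumerate(itos)}
        cts = [0, 0] + (list(counts) if counts is not None else [0] * len(words))
        return cls(index_to_word=itos, word_to_index=stoi, counts=cts)

    @property
    def size(self) -> int:
        return len(self.index_to_word)

    def __len__(self) -> int:
        return self.size

    def index(self, word: str) -> int:
        return self.word_to_index.get(word, UNK_INDEX)

    def word(self, index: int) -> str:
        return self.index_to_word[index]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["index", "word", "corpus_frequency"])
            for i, (w, c) in enumerate(zip(self.index_to_word, self.counts)):
                writer.writerow([i, w, c])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Vocabulary":
        words, counts = [], []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                if int(row["index"]) < 2:
                    continue
                words.append(row["word"])
                counts.append(int(row["corpus_frequency"]))
        return cls.from_words(words, counts=counts)


@dataclass
class EncodedDocument:
    """Token-index sequence plus class-index labels (None = missing)."""

    doc_id: str
    token_indices: np.ndarray  # int64, length >= 1
    labels: dict[str, int | None] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.token_indices)


def build_vocabulary(corpus: Iterable[RawRecord], min_count: int = 1) -> Vocabulary:
    """Count tokens over *corpus* and keep types with frequency >= *min_count*.

    Order is descending frequency then lexicographic, so the result is a pure
    function of the corpus and ``min_count``.
    """
    if min_count < 1:
        raise ConfigError("min_count must be >= 1")
    counter: Counter[str] = Counter()
    n_records = 0
    for rec in corpus:
        n_records += 1
        counter.update(tokenize(rec.text))
    if n_records == 0:
        raise ConfigError("cannot build a vocabulary from an empty corpus")
    kept = sorted(
        ((w, c) for w, c in counter.items() if c >= min_count),
        key=lambda wc: (-wc[1], wc[0]),
    )
    return Vocabulary.from_words([w for w, _ in kept], counts=[c for _, c in kept])


def encode(
    record: RawRecord,
    vocab: Vocabulary,
    schema: LabelSchema,
    max_len: int = 1500,
    truncate: str = "head",
) -> EncodedDocument:
    """Map a record to vocabulary indices and class indices.

    Out-of-vocabulary tokens become UNK; sequences longer than *max_len* are
    truncated (``truncate="head"`` keeps the earliest tokens — diagnosis fields
    typically lead a report — ``"tail"`` keeps the latest).  A record with zero
    tokens raises :class:`EmptyDocumentError`.
    """
    tokens = tokenize(record.text)
    if not tokens:
        raise EmptyDocumentError(record.doc_id)
    if truncate not in ("head", "tail"):
        raise ConfigError(f"unknown truncation mode {truncate!r}")
    if len(tokens) > max_len:
        tokens = tokens[:max_len] if truncate == "head" else tokens[-max_len:]
    indices = np.fromiter((vocab.index(t) for t in tokens), dtype=np.int64, count=len(tokens))
    labels: dict[str, int | None] = {}
    for task in schema.tasks:
        raw = record.labels.get(task)
        labels[task] = None if raw is None else schema.class_index(task, raw)
    return EncodedDocument(doc_id=record.doc_id, token_indices=indices, labels=labels)


def encode_corpus(records, vocab, schema, max_len: int = 1500, truncate: str = "head"):
    return [encode(r, vocab, schema, max_len=max_len, truncate=truncate) for r in records]
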