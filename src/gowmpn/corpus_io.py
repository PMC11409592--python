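"""On-disk artifacts: corpora, label schemas, predictions, metrics, checkpoints.

A corpus is JSON Lines (UTF-8, one record per line) with fields ``doc_id``
(string), ``text`` (string) and ``labels`` (object mapping task name to a
class-label string, or null for a missing label).  A label schema is a JSON
object ``{task: [class, ...]}`` whose task order is significant: it fixes the
order of the model's output heads.  Predictions are CSV, metrics JSON, and
checkpoints a single ``.npz`` archive holding every parameter table plus the
vocabulary, edge registry, schema and run configuration needed to rebuild the
model elsewhere — the point of the architecture is that a model trained at one
registry can be shipped to another without shipping any document.
"""

from __future__ import annotations

import csv
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import CheckpointError, CorpusFormatError, SchemaError

CHECKPOINT_VERSION = "gowmpn-checkpoint-1"


@dataclass(frozen=True)
class LabelSchema:
    """Ordered task registry: task names and, per task, an ordered class list."""

    tasks: tuple[str, ...]
    classes: Mapping[str, tuple[str, ...]]

    def __post_init__(self):
        if len(set(self.tasks)) != len(self.tasks):
            raise SchemaError("duplicate task names in schema")
        for task in self.tasks:
            cls = self.classes.get(task)
            if not cls:
                raise SchemaError(f"task {task!r} has an empty class list")
            if len(set(cls)) != len(cls):
                raise SchemaError(f"task {task!r} has duplicate class labels")
        if set(self.classes) != set(self.tasks):
            raise SchemaError("schema class mapping does not cover exactly the task list")

    def n_classes(self, task: str) -> int:
        return len(self.classes[task])

    def class_index(self, task: str, label: str) -> int:
        try:
            return self.classes[task].index(label)
        except ValueError:
            raise SchemaError(f"task {task!r}: unknown class label {label!r}") from None

    def restrict(self, task: str) -> "LabelSchema":
        """Single-task view used by ST-mode training."""
        if task not in self.tasks:
            raise SchemaError(f"unknown task {task!r}")
        return LabelSchema(tasks=(task,), classes={task: self.classes[task]})


@dataclass
class RawRecord:
    """One free-text document with (possibly partial) per-task labels."""

    doc_id: str
    text: str
    labels: dict[str, str | None] = field(default_factory=dict)


def read_label_schema(path: str | Path) -> LabelSchema:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    if not isinstance(obj, dict):
        raise SchemaError("schema file must contain a JSON object {task: [class, ...]}")
    return LabelSchema(tasks=tuple(obj.keys()), classes={t: tuple(c) for t, c in obj.items()})


def write_label_schema(schema: LabelSchema, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({t: list(schema.classes[t]) for t in schema.tasks}, fh, indent=1)
        fh.write("\n")


def _validate_labels(labels: dict, schema: LabelSchema, line_no: int) -> dict[str, str | None]:
    for task, label in labels.items():
        if task not in schema.classes:
            raise SchemaError(f"line {line_no}: unknown task {task!r}")
        if label is not None and label not in schema.classes[task]:
            raise SchemaError(f"line {line_no}: task {task!r} has no class {label!r}")
    return labels


def read_corpus(path: str | Path, schema: LabelSchema) -> list[RawRecord]:
    """Read a JSON Lines corpus, validating every label against *schema*.

    Records are returned in file order.  Malformed JSON raises
    :class:`CorpusFormatError` naming the line; an unknown task or class raises
    :class:`SchemaError`.
    """
    records: list[RawRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"invalid JSON: {exc.msg}", line_no) from exc
            if not isinstance(obj, dict) or "doc_id" not in obj or "text" not in obj:
                raise CorpusFormatError("record must be an object with doc_id and text", line_no)
            doc_id = str(obj["doc_id"])
            if doc_id in seen:
                raise CorpusFormatError(f"duplicate doc_id {doc_id!r}", line_no)
            seen.add(doc_id)
            labels = _validate_labels(dict(obj.get("labels") or {}), schema, line_no)
            records.append(RawRecord(doc_id=doc_id, text=str(obj["text"]), labels=labels))
    return records


def write_corpus(records: Iterable[RawRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(
                {"doc_id": rec.doc_id, "text": rec.text, "labels": rec.labels},
                ensure_ascii=False) + "\n")


def write_predictions(
    records: Sequence[tuple[str, Mapping[str, str], Mapping[str, float]]],
    schema: LabelSchema,
    path: str | Path,
) -> None:
    """Write per-document predictions as CSV.

    Each record is ``(doc_id, {task: argmax class}, {task: probability of that
    class})``; columns are ``doc_id``, one class column per task, then one
    probability column per task, probabilities with 6 decimal places.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        header = ["doc_id"] + [f"{t}_pred" for t in schema.tasks] + [f"{t}_prob" for t in schema.tasks]
        writer.writerow(header)
        for doc_id, preds, probs in records:
            missing = [t for t in schema.tasks if t not in preds or t not in probs]
            if missing:
                raise SchemaError(f"prediction for {doc_id!r} lacks tasks {missing}")
            row = [doc_id] + [preds[t] for t in schema.tasks]
            row += [f"{probs[t]:.6f}" for t in schema.tasks]
            writer.writerow(row)


def read_predictions(path: str | Path, schema: LabelSchema):
    """Inverse of :func:`write_predictions` (probabilities to 6 decimals)."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            preds = {t: row[f"{t}_pred"] for t in schema.tasks}
            probs = {t: float(row[f"{t}_prob"]) for t in schema.tasks}
            out.append((row["doc_id"], preds, probs))
    return out


def write_metrics(report: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)
        fh.write("\n")


def save_checkpoint(params, config: Mapping, path: str | Path) -> None:
    """Persist model parameters plus the full run configuration.

    *params* is a :class:`gowmpn.model.ModelParameters`; its vocabulary, edge
    registry and schema travel with it so that ``load_checkpoint`` is
    self-contained.  Round trip is bit-exact for every parameter table and
    verbatim for the configuration.
    """
    from .model import ModelParameters  # local import to avoid a cycle

    assert isinstance(params, ModelParameters)
    registry = params.registry
    pair_arr = np.array(sorted(registry.pair_to_edge_id), dtype=np.int64).reshape(-1, 2)
    pair_ids = np.array([registry.pair_to_edge_id[tuple(p)] for p in pair_arr], dtype=np.int64)
    arrays = {
        "version": np.array(CHECKPOINT_VERSION),
        "config_json": np.array(json.dumps(dict(config))),
        "schema_json": np.array(json.dumps({t: list(params.schema.classes[t])
                                            for t in params.schema.tasks})),
        "vocab_words": np.array(params.vocabulary.index_to_word[2:], dtype=object),
        "vocab_counts": np.asarray(params.vocabulary.counts[2:], dtype=np.int64),
        "registry_pairs": pair_arr,
        "registry_ids": pair_ids,
        "registry_self_loops": np.array(registry.self_loops),
        "embedding": params.embedding,
        "edge_weights": params.edge_weights,
    }
    if params.eta_raw is not None:
        arrays["eta_raw"] = params.eta_raw
    for task in params.schema.tasks:
        V, b = params.heads[task]
        arrays[f"head_V::{task}"] = V
        arrays[f"head_b::{task}"] = b
    # write through an open handle so the exact path is honoured (np.savez
    # appends .npz to bare string paths)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path: str | Path):
    """Load ``(ModelParameters, config dict)`` from a checkpoint file."""
    from .gow import EdgeRegistry
    from .model import ModelParameters
    from .preprocess import Vocabulary

    try:
        with np.load(path, allow_pickle=True) as data:
            files = dict(data)
    except (OSError, ValueError, zipfile.BadZipFile, KeyError) as exc:
        raise CheckpointError(f"unreadable checkpoint {path}: {exc}") from exc
    version = str(files.get("version"))
    if version != CHECKPOINT_VERSION:
        raise CheckpointError(
            f"checkpoint version {version!r} is incompatible with {CHECKPOINT_VERSION!r}")
    config = json.loads(str(files["config_json"]))
    schema_obj = json.loads(str(files["schema_json"]))
    schema = LabelSchema(tasks=tuple(schema_obj), classes={t: tuple(c) for t, c in schema_obj.items()})
    vocab = Vocabulary.from_words(
        [str(w) for w in files["vocab_words"]],
        counts=[int(c) for c in files["vocab_counts"]])
    pair_to_edge_id = {
        (int(a), int(n)): int(i)
        for (a, n), i in zip(files["registry_pairs"], files["registry_ids"])
    }
    registry = EdgeRegistry(pair_to_edge_id=pair_to_edge_id,
                            self_loops=bool(files["registry_self_loops"]))
    heads = {}
    for task in schema.tasks:
        try:
            heads[task] = (files[f"head_V::{task}"], files[f"head_b::{task}"])
        except KeyError as exc:
            raise CheckpointError(f"checkpoint lacks head for task {task!r}") from exc
    params = ModelParameters(
        vocabulary=vocab,
        registry=registry,
        schema=schema,
        embedding=files["embedding"],
        edge_weights=files["edge_weights"],
        eta_raw=files.get("eta_raw"),
        heads=heads,
    )
    return params, config
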