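"""Scikit-learn style front end.

:class:`GraphOfWordsClassifier` wires the whole pipeline — tokenization,
vocabulary, corpus-level edge registry, message-passing model, mini-batched
multi-task training and F1 evaluation — behind fit/predict/predict_proba, so
it composes with sklearn model selection.  ``X`` is a sequence of raw document
strings; ``y`` may be a pandas DataFrame (one column per task), a mapping of
task name to label sequence, a sequence of per-document ``{task: label}``
dicts, or a plain 1-D sequence for a single unnamed task.  ``None``/NaN labels
are treated as missing and masked from the loss.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .corpus_io import LabelSchema, RawRecord, load_checkpoint, save_checkpoint
from .errors import ConfigError
from .evaluate import evaluate_predictions
from .gow import GOWConfig, build_document_graph, build_edge_registry
from .model import ModelConfig, count_parameters
from .preprocess import build_vocabulary, encode_corpus
from .train import TrainConfig, predict_proba_docs, train


def _labels_to_dicts(y, n_docs: int) -> tuple[list[str], list[dict]]:
    """Normalize any accepted label container to (task order, per-doc dicts)."""
    def clean(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return str(v)

    if isinstance(y, pd.DataFrame):
        tasks = [str(c) for c in y.columns]
        dicts = [{t: clean(v) for t, v in zip(tasks, row)} for row in y.itertuples(index=False)]
    elif isinstance(y, Mapping):
        tasks = list(y)
        cols = {t: list(y[t]) for t in tasks}
        dicts = [{t: clean(cols[t][i]) for t in tasks} for i in range(n_docs)]
    elif len(y) and isinstance(y[0], Mapping):
        tasks = []
        for d in y:
            for t in d:
                if t not in tasks:
                    tasks.append(t)
        dicts = [{t: clean(d.get(t)) for t in tasks} for d in y]
    else:
        tasks = ["label"]
        dicts = [{"label": clean(v)} for v in y]
    if len(dicts) != n_docs:
        raise ConfigError(f"y has {len(dicts)} rows for {n_docs} documents")
    return tasks, dicts


class GraphOfWordsClassifier(ClassifierMixin, BaseEstimator):
    """Multi-task text classifier over graph-of-words message passing.

    Parameters follow the pipeline stages: ``window`` is the co-occurrence
    distance d; ``embedding_dim`` the node-embedding length w; ``aggregation``
    one of ``max`` (reference rule with optional retention), ``dense_sum``
    (full adjacency product) or ``sparse_sum`` (gather/scatter, the default);
    ``dropout`` applies to the pooled document vector during training.
    ``mode="ST"`` with ``task`` trains a single-task model.  The trained
    parameters live in ``params_``; per-epoch history in ``history_``.
    """

    def __init__(
        self,
        *,
        window: int = 10,
        edge_min_count: int = 1,
        self_loops: bool = True,
        embedding_dim: int = 300,
        aggregation: str = "sparse_sum",
        n_layers: int = 1,
        use_eta: bool = False,
        activation: str = "relu",
        dropout: float = 0.25,
        min_count: int = 1,
        max_len: int = 1500,
        truncate: str = "head",
        batch_size: int = 256,
        learning_rate: float = 1e-3,
        n_epochs: int = 30,
        patience: int = 5,
        mode: str = "MT",
        task: str | None = None,
        trainable_embedding: bool = True,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.window = window
        self.edge_min_count = edge_min_count
        self.self_loops = self_loops
        self.embedding_dim = embedding_dim
        self.aggregation = aggregation
        self.n_layers = n_layers
        self.use_eta = use_eta
        self.activation = activation
        self.dropout = dropout
        self.min_count = min_count
        self.max_len = max_len
        self.truncate = truncate
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.patience = patience
        self.mode = mode
        self.task = task
        self.trainable_embedding = trainable_embedding
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _configs(self):
        gow = GOWConfig(window=self.window, edge_min_count=self.edge_min_count,
                        self_loops=self.self_loops)
        model = ModelConfig(embedding_dim=self.embedding_dim,
                            aggregation=self.aggregation, n_layers=self.n_layers,
                            use_eta=self.use_eta, activation=self.activation,
                            dropout=self.dropout)
        tr = TrainConfig(batch_size=self.batch_size,
                         learning_rate=self.learning_rate,
                         n_epochs=self.n_epochs, patience=self.patience,
                         seed=self.random_state, mode=self.mode, task=self.task,
                         trainable_embedding=self.trainable_embedding)
        return gow, model, tr

    def fit(self, X: Sequence[str], y, schema: LabelSchema | None = None,
            validation_data=None):
        """Fit on raw texts.

        ``schema`` fixes task order and class registries explicitly; otherwise
        both are derived from ``y`` (classes in sorted order).
        ``validation_data`` is an optional ``(X_val, y_val)`` pair; without it
        a seeded ``validation_fraction`` split of the training data is used
        for early stopping.
        """
        X = list(X)
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ConfigError("validation_fraction must lie in [0, 1)")
        tasks, dicts = _labels_to_dicts(y, len(X))
        if schema is None:
            classes = {
                t: tuple(sorted({d[t] for d in dicts if d[t] is not None}))
                for t in tasks
            }
            schema = LabelSchema(tasks=tuple(tasks), classes=classes)
        records = [RawRecord(doc_id=f"train{i:07d}", text=text, labels=d)
                   for i, (text, d) in enumerate(zip(X, dicts))]
        if validation_data is not None:
            X_val, y_val = validation_data
            _, val_dicts = _labels_to_dicts(y_val, len(X_val))
            val_records = [RawRecord(doc_id=f"val{i:07d}", text=t, labels=d)
                           for i, (t, d) in enumerate(zip(X_val, val_dicts))]
            train_records = records
        else:
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(len(records))
            n_val = int(round(self.validation_fraction * len(records)))
            val_idx = set(order[:n_val].tolist())
            train_records = [r for i, r in enumerate(records) if i not in val_idx]
            val_records = [r for i, r in enumerate(records) if i in val_idx]
        if not train_records:
            raise ConfigError("no training documents after validation split")

        gow_config, model_config, train_config = self._configs()
        vocab = build_vocabulary(train_records, min_count=self.min_count)
        enc_train = encode_corpus(train_records, vocab, schema,
                                  max_len=self.max_len, truncate=self.truncate)
        enc_val = encode_corpus(val_records, vocab, schema,
                                max_len=self.max_len, truncate=self.truncate)
        registry = build_edge_registry(enc_train, gow_config, vocab.size)
        params, log = train(enc_train, enc_val, registry, schema,
                            model_config, train_config, gow_config, vocab)
        self.schema_ = params.schema
        self.vocabulary_ = vocab
        self.registry_ = registry
        self.params_ = params
        self.history_ = log
        self.tasks_ = list(params.schema.tasks)
        self.classes_per_task_ = {t: np.asarray(params.schema.classes[t])
                                  for t in self.tasks_}
        if len(self.tasks_) == 1:
            self.classes_ = self.classes_per_task_[self.tasks_[0]]
        return self

    # ------------------------------------------------------------------
    def _encode_for_inference(self, X: Sequence[str]):
        gow_config, _, _ = self._configs()
        records = [RawRecord(doc_id=f"infer{i:07d}", text=t, labels={})
                   for i, t in enumerate(X)]
        docs = encode_corpus(records, self.vocabulary_, self.schema_,
                             max_len=self.max_len, truncate=self.truncate)
        graphs = [build_document_graph(d, self.registry_, gow_config) for d in docs]
        return docs, graphs

    def predict_proba(self, X: Sequence[str]):
        """Per-task class probabilities; a bare array for single-task models."""
        self._check_fitted()
        docs, graphs = self._encode_for_inference(X)
        _, model_config, _ = self._configs()
        probs = predict_proba_docs(docs, graphs, self.params_, model_config,
                                   batch_size=self.batch_size)
        if len(self.tasks_) == 1:
            return probs[self.tasks_[0]]
        return probs

    def predict(self, X: Sequence[str]):
        """Argmax class labels: a DataFrame for multi-task, 1-D for single-task."""
        self._check_fitted()
        probs = self.predict_proba(X)
        if len(self.tasks_) == 1:
            task = self.tasks_[0]
            return self.classes_per_task_[task][probs.argmax(axis=1)]
        data = {t: self.classes_per_task_[t][probs[t].argmax(axis=1)]
                for t in self.tasks_}
        return pd.DataFrame(data, columns=self.tasks_)

    def score(self, X: Sequence[str], y, sample_weight=None) -> float:
        """Mean of per-task micro/macro F1 (the 2 x n_tasks aggregate)."""
        report = self.evaluate(X, y)
        return report["aggregate"]

    def evaluate(self, X: Sequence[str], y) -> dict:
        """Full evaluation report against labels in any accepted container."""
        self._check_fitted()
        _, dicts = _labels_to_dicts(y, len(list(X)))
        probs = self.predict_proba(X)
        if len(self.tasks_) == 1:
            probs = {self.tasks_[0]: probs}
        truth, pred = {}, {}
        for t in self.tasks_:
            idx = [i for i, d in enumerate(dicts) if d.get(t) is not None]
            truth[t] = np.array([self.schema_.class_index(t, dicts[i][t]) for i in idx])
            pred[t] = probs[t][idx].argmax(axis=1)
        return evaluate_predictions(truth, pred, self.schema_)

    # ------------------------------------------------------------------
    def count_parameters(self, include_sentinels: bool = True) -> dict[str, int]:
        self._check_fitted()
        _, model_config, _ = self._configs()
        return count_parameters(self.vocabulary_, self.registry_, self.schema_,
                                model_config, include_sentinels=include_sentinels)

    def save(self, path) -> None:
        """Persist the fitted model (parameters + constructor configuration)."""
        self._check_fitted()
        save_checkpoint(self.params_, self.get_params(), path)

    @classmethod
    def load(cls, path) -> "GraphOfWordsClassifier":
        params, config = load_checkpoint(path)
        est = cls(**config)
        est.schema_ = params.schema
        est.vocabulary_ = params.vocabulary
        est.registry_ = params.registry
        est.params_ = params
        est.history_ = []
        est.tasks_ = list(params.schema.tasks)
        est.classes_per_task_ = {t: np.asarray(params.schema.classes[t])
                                 for t in est.tasks_}
        if len(est.tasks_) == 1:
            est.classes_ = est.classes_per_task_[est.tasks_[0]]
        return est

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise ConfigError("this GraphOfWordsClassifier instance is not fitted yet")
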