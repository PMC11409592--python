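"""Micro/macro-averaged F1 evaluation and the cross-task aggregate.

The six extraction tasks are severely class-imbalanced, so both views matter:
micro-averaged F1 pools true/false positive/negative counts globally (for
single-label multiclass prediction it coincides with accuracy), while
macro-averaged F1 is the unweighted mean of per-class F1 and is sensitive to
minority classes.  To compare models across 6 tasks x 2 scores at a glance,
the arithmetic mean of all 12 scores is reported as a single aggregate; it is
a comparison statistic only and carries no clinical meaning.

Macro averaging runs over the classes observed in the truth or the
predictions (configurable to the full class registry): tasks with hundreds of
registered classes never realize them all in a finite test set.  A per-class
F1 with a zero denominator is defined as 0.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score, precision_recall_fscore_support

from .corpus_io import LabelSchema
from .errors import ConfigError


def _check_lengths(truth, predicted):
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape or truth.ndim != 1:
        raise ConfigError("truth and predictions must be 1-D and of equal length")
    if len(truth) == 0:
        raise ConfigError("cannot score an empty prediction set")
    return truth, predicted


def micro_f1(truth: Sequence[int], predicted: Sequence[int]) -> float:
    """F1 from globally pooled counts; equals accuracy for single-label output."""
    truth, predicted = _check_lengths(truth, predicted)
    return float(f1_score(truth, predicted, average="micro", zero_division=0))


def macro_f1(
    truth: Sequence[int],
    predicted: Sequence[int],
    class_universe: Sequence[int] | None = None,
) -> float:
    """Unweighted mean of per-class F1.

    By default the mean runs over classes present in truth or predictions;
    pass ``class_universe`` to average over a fixed registry instead.
    """
    truth, predicted = _check_lengths(truth, predicted)
    if class_universe is None:
        labels = np.unique(np.concatenate([truth, predicted]))
    else:
        labels = np.asarray(sorted(class_universe))
    return float(f1_score(truth, predicted, labels=labels, average="macro",
                          zero_division=0))


def aggregate_scores(scores: Sequence[float]) -> float:
    """Arithmetic mean of a flat list of F1 scores (e.g. 6 tasks x 2 views)."""
    if len(scores) == 0:
        raise ConfigError("cannot aggregate an empty score list")
    return float(np.mean(np.asarray(scores, dtype=float)))


def evaluate_predictions(
    truth: Mapping[str, Sequence[int]],
    predicted: Mapping[str, Sequence[int]],
    schema: LabelSchema,
    class_universe: str = "observed",
) -> dict:
    """Full report: per-task micro/macro F1, per-class table, confusions,
    and the 2 x n_tasks aggregate.

    ``class_universe`` is "observed" (default) or "registry".
    """
    if class_universe not in ("observed", "registry"):
        raise ConfigError("class_universe must be 'observed' or 'registry'")
    tasks_out: dict[str, dict] = {}
    flat: list[float] = []
    per_class: dict[str, list[dict]] = {}
    confusions: dict[str, dict] = {}
    for task in schema.tasks:
        t = np.asarray(truth[task])
        p = np.asarray(predicted[task])
        if len(t) == 0:
            raise ConfigError(f"no scored documents for task {task!r}")
        universe = (range(schema.n_classes(task)) if class_universe == "registry"
                    else None)
        mi = micro_f1(t, p)
        ma = macro_f1(t, p, class_universe=universe)
        tasks_out[task] = {"micro_f1": mi, "macro_f1": ma}
        flat.extend([mi, ma])
        labels = (np.unique(np.concatenate([t, p])) if universe is None
                  else np.asarray(sorted(universe)))
        prec, rec, f1c, support = precision_recall_fscore_support(
            t, p, labels=labels, zero_division=0)
        per_class[task] = [
            {"class_index": int(c), "class": schema.classes[task][int(c)],
             "precision": float(pr), "recall": float(rc), "f1": float(f),
             "support": int(s)}
            for c, pr, rc, f, s in zip(labels, prec, rec, f1c, support)
        ]
        cm = confusion_matrix(t, p, labels=labels)
        confusions[task] = {"labels": [int(c) for c in labels],
                            "counts": cm.tolist()}
    return {
        "tasks": tasks_out,
        "aggregate": aggregate_scores(flat),
        "per_class": per_class,
        "confusion": confusions,
    }
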