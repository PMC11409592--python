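"""Synthetic pathology-report-like corpus generator.

Real registry corpora cannot be shared, so every stage of the pipeline is
exercised on generated documents that reproduce the *structure* of the real
task: short semi-structured clinical phrases, six correlated label tasks with
very different class counts, severe class imbalance, and surface variability
of expression.  Each document renders one field phrase per non-omitted task
("histologic grade: 3", "laterality: left", ...), drawn from that class's
template family, with three independent variation operators:

* word inversion            "poorly differentiated" -> "differentiated poorly"
* parenthetical insertion   "histologic grade: 3" -> "histologic grade (mbr): 3"
* synonym substitution      "3" <-> "g3" <-> "iii" <-> "poorly differentiated"

plus interleaved filler sentences and (optionally) random noise tokens.
Class priors follow a power law over class rank; the subsite label is always
consistent with the site label (two subsites nest under each site).  Field
omission produces records with missing labels, exercising the loss mask.

With noise off, the label is a deterministic function of the rendered text:
:func:`rule_based_labels` recovers every label exactly, which guarantees the
classification problem is solvable and makes near-perfect model F1 an
achievable training target.  All templates are fictional.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import LabelSchema, RawRecord
from .errors import ConfigError
from .preprocess import tokenize

TASKS = ("site", "subsite", "laterality", "histology", "behavior", "grade")

# Each class: ordered list of surface forms (first form is canonical and is
# used as the class-label string).  Within a task, every class owns at least
# one token no other class's form uses, so subset matching is unambiguous.
_SITE_FORMS = {
    "lung": ["lung", "pulmonary"],
    "breast": ["breast", "mammary"],
    "colon": ["colon", "colonic"],
    "prostate": ["prostate", "prostatic"],
    "kidney": ["kidney", "renal"],
    "skin": ["skin", "cutaneous"],
}
_SUBSITE_FORMS = {
    "upper lobe": ["upper lobe"],
    "lower lobe": ["lower lobe"],
    "outer quadrant": ["outer quadrant"],
    "central portion": ["central portion"],
    "sigmoid segment": ["sigmoid segment"],
    "ascending segment": ["ascending segment"],
    "peripheral zone": ["peripheral zone"],
    "transition zone": ["transition zone"],
    "pelvis region": ["pelvis region"],
    "cortex region": ["cortex region"],
    "trunk surface": ["trunk surface"],
    "scalp surface": ["scalp surface"],
}
_SITE_SUBSITES = {
    "lung": ["upper lobe", "lower lobe"],
    "breast": ["outer quadrant", "central portion"],
    "colon": ["sigmoid segment", "ascending segment"],
    "prostate": ["peripheral zone", "transition zone"],
    "kidney": ["pelvis region", "cortex region"],
    "skin": ["trunk surface", "scalp surface"],
}
_LATERALITY_FORMS = {
    "left": ["left", "lt"],
    "right": ["right", "rt"],
    "bilateral": ["bilateral", "both sides"],
    "unknown": ["unknown", "not specified"],
}
_HISTOLOGY_FORMS = {
    "adenocarcinoma": ["adenocarcinoma", "adeno carcinoma"],
    "squamous cell carcinoma": ["squamous cell carcinoma", "squamous carcinoma"],
    "ductal carcinoma": ["ductal carcinoma"],
    "lobular carcinoma": ["lobular carcinoma"],
    "melanoma": ["melanoma"],
    "sarcoma": ["sarcoma"],
    "lymphoma": ["lymphoma"],
    "carcinoid tumor": ["carcinoid tumor", "carcinoid"],
    "papillary carcinoma": ["papillary carcinoma"],
    "mucinous carcinoma": ["mucinous carcinoma"],
}
_BEHAVIOR_FORMS = {
    "benign": ["benign"],
    "in situ": ["in situ"],
    "malignant": ["malignant", "invasive"],
}
_GRADE_FORMS = {
    "1": ["1", "g1", "i", "well differentiated"],
    "2": ["2", "g2", "ii", "moderately differentiated"],
    "3": ["3", "g3", "iii", "poorly differentiated"],
    "4": ["4", "g4", "undifferentiated"],
    "unknown": ["gx", "not determined"],
}
_ALL_FORMS = {
    "site": _SITE_FORMS,
    "subsite": _SUBSITE_FORMS,
    "laterality": _LATERALITY_FORMS,
    "histology": _HISTOLOGY_FORMS,
    "behavior": _BEHAVIOR_FORMS,
    "grade": _GRADE_FORMS,
}
_FIELD_PREFIX = {
    "site": "primary site:",
    "subsite": "subsite:",
    "laterality": "laterality:",
    "histology": "histology:",
    "behavior": "behavior:",
    "grade": "histologic grade:",
}
# the token that opens each field segment (see rule_based_labels)
_KEYWORD_TO_TASK = {
    "site": "site", "subsite": "subsite", "laterality": "laterality",
    "histology": "histology", "behavior": "behavior", "grade": "grade",
}
_PARENTHETICALS = ["mbr", "nos", "see note", "per protocol"]
_DECOY_TOKENS = {t for p in _PARENTHETICALS for t in tokenize(p)}
_FILLERS = [
    "specimen received fresh for evaluation",
    "microscopic examination performed",
    "clinical history noted by the pathologist",
    "gross description a tan firm mass measuring several mm",
    "immunostains were examined and reported",
    "final diagnosis follows below",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Corpus size, seed, class counts, imbalance and variation rates.

    Class counts may be reduced below the template capacity (site <= 6,
    subsite fixed at 2 per site, laterality <= 4, histology <= 10,
    behavior <= 3, grade <= 5); the imbalance exponent alpha sets a power-law
    prior p(class rank i) proportional to (i+1)^-alpha per task.
    """

    n_documents: int = 5000
    seed: int = 0
    n_site: int = 6
    n_laterality: int = 4
    n_histology: int = 10
    n_behavior: int = 3
    n_grade: int = 5
    imbalance_exponent: float = 1.5
    p_invert: float = 0.3
    p_parenthetical: float = 0.3
    p_synonym: float = 0.5
    p_omit: float = 0.08
    noise_token_rate: float = 0.0
    filler_range: tuple[int, int] = (1, 3)

    def __post_init__(self):
        for name in ("p_invert", "p_parenthetical", "p_synonym", "p_omit",
                     "noise_token_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        limits = {"n_site": 6, "n_laterality": 4, "n_histology": 10,
                  "n_behavior": 3, "n_grade": 5}
        for name, hi in limits.items():
            v = getattr(self, name)
            if not 2 <= v <= hi:
                raise ConfigError(f"{name} must lie in [2, {hi}], got {v}")
        if self.n_documents < 0:
            raise ConfigError("n_documents must be >= 0")
        lo, hi = self.filler_range
        if not 0 <= lo <= hi:
            raise ConfigError("filler_range must be a non-decreasing pair >= 0")

    @property
    def n_subsite(self) -> int:
        return 2 * self.n_site  # two subsites nest under every site

    def class_lists(self) -> dict[str, list[str]]:
        sites = list(_SITE_FORMS)[: self.n_site]
        return {
            "site": sites,
            "subsite": [s for site in sites for s in _SITE_SUBSITES[site]],
            "laterality": list(_LATERALITY_FORMS)[: self.n_laterality],
            "histology": list(_HISTOLOGY_FORMS)[: self.n_histology],
            "behavior": list(_BEHAVIOR_FORMS)[: self.n_behavior],
            "grade": list(_GRADE_FORMS)[: self.n_grade],
        }


@dataclass
class SyntheticRecord:
    """A RawRecord plus the latent template choices that produced it."""

    record: RawRecord
    latents: dict = field(default_factory=dict)


def build_schema(config: GeneratorConfig) -> LabelSchema:
    lists = config.class_lists()
    return LabelSchema(tasks=TASKS, classes={t: tuple(lists[t]) for t in TASKS})


def _power_law(n: int, alpha: float) -> np.ndarray:
    p = (np.arange(1, n + 1, dtype=float)) ** (-alpha)
    return p / p.sum()


def class_priors(config: GeneratorConfig) -> dict[str, np.ndarray]:
    """Marginal class priors implied by the configuration.

    The subsite marginal is the site prior spread over each site's two
    subsites with a (renormalized) power split.
    """
    lists = config.class_lists()
    priors = {t: _power_law(len(lists[t]), config.imbalance_exponent)
              for t in ("site", "laterality", "histology", "behavior", "grade")}
    split = _power_law(2, config.imbalance_exponent)
    priors["subsite"] = np.concatenate([p * split for p in priors["site"]])
    return priors


def _render_field(task, label, rng, config):
    forms = _ALL_FORMS[task][label]
    if len(forms) > 1 and rng.random() < config.p_synonym:
        form = forms[int(rng.integers(1, len(forms)))]
    else:
        form = forms[0]
    words = form.split()
    inverted = False
    if len(words) > 1 and rng.random() < config.p_invert:
        words = words[::-1]
        inverted = True
    prefix = _FIELD_PREFIX[task]
    paren = None
    if rng.random() < config.p_parenthetical:
        paren = _PARENTHETICALS[int(rng.integers(len(_PARENTHETICALS)))]
        head, _, tail = prefix.partition(":")
        prefix = f"{head} ({paren}):{tail}"
    return f"{prefix} {' '.join(words)}", {"form": form, "inverted": inverted,
                                           "parenthetical": paren}


def _noise_token(rng) -> str:
    letters = "abcdefghijklmnopqrstuvwxyz"
    return "zz" + "".join(letters[int(i)] for i in rng.integers(0, 26, size=3))


def generate_corpus(config: GeneratorConfig) -> list[SyntheticRecord]:
    """Seeded-deterministic corpus generation; see the module docstring."""
    rng = np.random.default_rng(config.seed)
    lists = config.class_lists()
    priors = {t: _power_law(len(lists[t]), config.imbalance_exponent)
              for t in ("site", "laterality", "histology", "behavior", "grade")}
    subsite_split = _power_law(2, config.imbalance_exponent)
    out: list[SyntheticRecord] = []
    for i in range(config.n_documents):
        labels: dict[str, str | None] = {}
        site = lists["site"][int(rng.choice(len(lists["site"]), p=priors["site"]))]
        labels["site"] = site
        labels["subsite"] = _SITE_SUBSITES[site][
            int(rng.choice(2, p=subsite_split))]
        for task in ("laterality", "histology", "behavior", "grade"):
            labels[task] = lists[task][
                int(rng.choice(len(lists[task]), p=priors[task]))]
        latents: dict = {"true_labels": dict(labels)}
        sentences: list[str] = []
        emitted: dict[str, str | None] = {}
        for task in TASKS:
            if rng.random() < config.p_omit:
                emitted[task] = None
                continue
            phrase, lat = _render_field(task, labels[task], rng, config)
            latents[task] = lat
            sentences.append(phrase)
            emitted[task] = labels[task]
        n_filler = int(rng.integers(config.filler_range[0],
                                    config.filler_range[1] + 1))
        if not sentences and n_filler == 0:
            n_filler = 1  # never emit an empty document
        for _ in range(n_filler):
            pos = int(rng.integers(0, len(sentences) + 1))
            sentences.insert(pos, _FILLERS[int(rng.integers(len(_FILLERS)))])
        text = ". ".join(sentences) + "."
        if config.noise_token_rate > 0.0:
            words = text.split()
            noisy = []
            for wtok in words:
                noisy.append(wtok)
                if rng.random() < config.noise_token_rate:
                    noisy.append(_noise_token(rng))
            text = " ".join(noisy)
        out.append(SyntheticRecord(
            record=RawRecord(doc_id=f"doc{i:06d}", text=text, labels=emitted),
            latents=latents))
    return out


def rule_based_labels(text: str, config: GeneratorConfig) -> dict[str, str | None]:
    """Recover labels from rendered text by template matching.

    Tokens are segmented at the task keywords; within a segment, decoy
    parenthetical tokens are dropped and a class matches when the token set of
    any of its surface forms is contained in the segment's token set.  With
    generator noise off this recovers every non-omitted label exactly.
    """
    lists = config.class_lists()
    tokens = tokenize(text)
    segments: dict[str, set[str]] = {}
    current: str | None = None
    for tok in tokens:
        task = _KEYWORD_TO_TASK.get(tok)
        if task is not None:
            current = task
            segments.setdefault(task, set())
            continue
        if current is not None and tok not in _DECOY_TOKENS:
            segments[current].add(tok)
    out: dict[str, str | None] = {}
    for task in TASKS:
        seg = segments.get(task)
        match = None
        if seg:
            hits = [
                label for label in lists[task]
                if any(set(tokenize(form)) <= seg for form in _ALL_FORMS[task][label])
            ]
            if len(hits) == 1:
                match = hits[0]
        out[task] = match
    return out


def corpus_summary(corpus: Sequence[SyntheticRecord]) -> dict:
    """Per-task class histogram, vocabulary size and mean document length."""
    hist: dict[str, Counter] = {t: Counter() for t in TASKS}
    vocab: set[str] = set()
    lengths: list[int] = []
    for item in corpus:
        rec = item.record
        toks = tokenize(rec.text)
        vocab.update(toks)
        lengths.append(len(toks))
        for task, label in rec.labels.items():
            if label is not None:
                hist[task][label] += 1
    return {
        "n_documents": len(corpus),
        "class_histograms": {t: dict(hist[t]) for t in TASKS},
        "vocabulary_size": len(vocab),
        "mean_document_length": float(np.mean(lengths)) if lengths else 0.0,
    }
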