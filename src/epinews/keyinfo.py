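"""Key-entity extraction: the most-frequent heuristic and the
key-sentence classifier.

An outbreak article mentions many diseases, places, dates and counts;
the incident database wants exactly one of each.  Two filters produce
that single value:

* the **most-frequent approach** — take the modal value among a class's
  mentions (restricted to the first three mentions for geography, since
  the key country tends to be named early) — works well for disease and
  country;
* the **key-sentence approach** — train a naive Bayes classifier to
  recognise the sentence carrying the database-worthy fact, then return
  the date/count mentioned in the sentence with the highest posterior of
  being *key*.  A value is returned even when every sentence scores
  below 0.5: the best candidate is still the best candidate.

The naive Bayes implementation is self-contained (closed-form posterior,
Laplace smoothing with ``alpha = 1``, JSON serialisation).  The
Bernoulli variant consumes binary presence vectors; the multinomial
variant consumes tf-idf-weighted count vectors with document
frequencies frozen on the training sentences.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .annotate import AnnotatedDocument, EntityMention
from .corpus import GoldRecord
from .features import (
    BowVector,
    TfidfWeighter,
    Vocabulary,
    binarize,
    build_vocabulary,
    count_vector,
    tokenize,
)

__all__ = [
    "SentenceExample",
    "NaiveBayesModel",
    "KeyExtractionResult",
    "most_frequent_key",
    "build_sentence_dataset",
    "fit_naive_bayes",
    "predict_key_probability",
    "select_key_entity",
    "extract_all",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

Label = Literal["key", "not_key"]


@dataclass(frozen=True)
class SentenceExample:
    """One training sentence for the key-sentence classifier.  Only
    sentences containing at least one mention of the target class become
    examples."""

    article_id: str
    sentence_index: int
    tokens: tuple[str, ...]
    label: Label
    entity_classes: frozenset[str] = frozenset()


def most_frequent_key(
    mentions: Sequence[EntityMention],
    entity_class: str,
    first_k: int | None = None,
):
    """Modal value among the first ``first_k`` mentions of a class (all
    mentions if ``first_k`` is None); ties break toward the value whose
    first occurrence is earliest.  Returns None when there are no
    mentions."""
    values = [m.value for m in mentions if m.entity_class == entity_class]
    if first_k is not None:
        values = values[:first_k]
    if not values:
        return None
    counts = Counter(values)
    best = max(counts.values())
    for value in values:  # text order => earliest first occurrence wins ties
        if counts[value] == best:
            return value
    raise AssertionError("unreachable")


def build_sentence_dataset(
    docs: Sequence[AnnotatedDocument],
    gold: Sequence[GoldRecord],
    entity_class: Literal["date", "count"],
    date_window_days: int = 3,
) -> list[SentenceExample]:
    """Label sentences against the gold records.

    A sentence is *key* iff it contains a mention of ``entity_class``
    whose value matches the gold value (counts: exact equality; dates:
    within ``date_window_days`` days, matching the evaluation rule).
    Sentences without any mention of the class are excluded; articles
    without a gold record are skipped with a warning.
    """
    by_id = {g.article_id: g for g in gold}
    examples: list[SentenceExample] = []
    for doc in docs:
        record = by_id.get(doc.article.id)
        if record is None:
            logger.warning("no gold record for article %r; skipped", doc.article.id)
            continue
        target = record.date if entity_class == "date" else record.confirmed_case_count
        per_sentence: dict[int, list[EntityMention]] = {}
        classes_in_sentence: dict[int, set[str]] = {}
        for m in doc.mentions:
            classes_in_sentence.setdefault(m.sentence_index, set()).add(m.entity_class)
            if m.entity_class == entity_class:
                per_sentence.setdefault(m.sentence_index, []).append(m)
        for index, ms in sorted(per_sentence.items()):
            if entity_class == "date":
                hit = any(abs((m.value - target).days) <= date_window_days for m in ms)
            else:
                hit = any(m.value == target for m in ms)
            examples.append(
                SentenceExample(
                    article_id=doc.article.id,
                    sentence_index=index,
                    tokens=tuple(tokenize(doc.sentences[index][1])),
                    label="key" if hit else "not_key",
                    entity_classes=frozenset(classes_in_sentence.get(index, set())),
                )
            )
    return examples


@dataclass
class NaiveBayesModel:
    """Two-class naive Bayes over a fixed vocabulary.

    ``log_prior`` maps label -> log P(label).  For the Bernoulli variant
    ``feature_params[label]`` holds per-term Bernoulli probabilities
    P(t present | label); for the multinomial variant it holds per-term
    event probabilities theta_{t, label} estimated from tf-idf-weighted
    counts.  ``idf`` / ``n_documents`` carry the frozen tf-idf state for
    the multinomial variant.
    """

    variant: Literal["bernoulli", "multinomial"]
    vocabulary: Vocabulary
    log_prior: dict[str, float]
    feature_params: dict[str, np.ndarray]
    smoothing: float = 1.0
    idf: np.ndarray | None = None
    n_documents: int | None = None

    def _tfidf(self, counts: np.ndarray) -> np.ndarray:
        max_f = counts.max() if counts.size else 0.0
        if max_f == 0:
            return np.zeros_like(counts)
        return np.maximum((counts / max_f) * self.idf, 0.0)

    def log_joint(self, tokens: Sequence[str]) -> dict[str, float]:
        """Un-normalised log P(label, sentence) per label."""
        out: dict[str, float] = {}
        if self.variant == "bernoulli":
            x = binarize(tokens, self.vocabulary).values
            for label, p in self.feature_params.items():
                ll = np.sum(x * np.log(p) + (1.0 - x) * np.log1p(-p))
                out[label] = self.log_prior[label] + float(ll)
        else:
            counts = count_vector(tokens, self.vocabulary).values
            w = self._tfidf(counts)
            for label, theta in self.feature_params.items():
                out[label] = self.log_prior[label] + float(np.sum(w * np.log(theta)))
        return out


def fit_naive_bayes(
    examples: Sequence[SentenceExample],
    variant: Literal["bernoulli", "multinomial"] = "bernoulli",
) -> NaiveBayesModel:
    """Fit a Laplace-smoothed naive Bayes key-sentence classifier.

    Both labels must be present.  The Bernoulli variant sees binary
    presence vectors; the multinomial variant sees tf-idf-weighted count
    vectors (the tf-idf state is stored on the model so prediction uses
    the training document frequencies).
    """
    labels = {e.label for e in examples}
    if labels != {"key", "not_key"}:
        raise ValueError(
            f"training set must contain both labels; got {sorted(labels)}"
        )
    vocab = build_vocabulary([e.tokens for e in examples])
    n = len(examples)
    alpha = 1.0
    log_prior = {}
    feature_params: dict[str, np.ndarray] = {}
    idf = None
    n_documents = None

    if variant == "bernoulli":
        for label in ("key", "not_key"):
            members = [e for e in examples if e.label == label]
            log_prior[label] = math.log(len(members) / n)
            x = np.stack([binarize(e.tokens, vocab).values for e in members])
            # P(t | label) = (docs containing t + 1) / (docs + 2)
            feature_params[label] = (x.sum(axis=0) + alpha) / (len(members) + 2 * alpha)
    elif variant == "multinomial":
        counts = [count_vector(e.tokens, vocab) for e in examples]
        weighter = TfidfWeighter().fit(counts)
        idf, n_documents = weighter.idf, weighter.n_documents
        weighted = np.stack([weighter.transform(c).values for c in counts])
        for label in ("key", "not_key"):
            mask = np.array([e.label == label for e in examples])
            log_prior[label] = math.log(mask.sum() / n)
            totals = weighted[mask].sum(axis=0)
            feature_params[label] = (totals + alpha) / (totals.sum() + alpha * len(vocab))
    else:
        raise ValueError(f"unknown variant {variant!r}")

    return NaiveBayesModel(
        variant=variant,
        vocabulary=vocab,
        log_prior=log_prior,
        feature_params=feature_params,
        smoothing=alpha,
        idf=idf,
        n_documents=n_documents,
    )


def predict_key_probability(model: NaiveBayesModel, tokens: Sequence[str]) -> float:
    """Normalised two-class posterior P(key | sentence)."""
    joint = model.log_joint(tokens)
    a, b = joint["key"], joint["not_key"]
    m = max(a, b)
    return math.exp(a - m) / (math.exp(a - m) + math.exp(b - m))


@dataclass
class KeyExtractionResult:
    """The single extracted value per entity class (any may be None),
    with the key-sentence posterior for the classifier-derived classes."""

    disease: str | None = None
    country: str | None = None
    date: Date | None = None
    count: int | None = None
    date_probability: float | None = None
    count_probability: float | None = None


def select_key_entity(
    model: NaiveBayesModel,
    doc: AnnotatedDocument,
    entity_class: Literal["date", "count"],
):
    """Pick the mention of ``entity_class`` from the sentence with the
    highest posterior of being key.

    Among sentences containing at least one mention of the class, take
    the argmax posterior (first sentence wins ties) and return that
    sentence's first mention of the class by offset, together with the
    posterior — even when every posterior is below 0.5.  Returns None
    only when the document has no mention of the class at all.
    """
    candidates: dict[int, list[EntityMention]] = {}
    for m in doc.mentions:
        if m.entity_class == entity_class:
            candidates.setdefault(m.sentence_index, []).append(m)
    if not candidates:
        return None
    best_index, best_prob = None, -1.0
    for index in sorted(candidates):
        prob = predict_key_probability(model, tokenize(doc.sentences[index][1]))
        if prob > best_prob:
            best_index, best_prob = index, prob
    mention = min(candidates[best_index], key=lambda m: m.start)
    return mention.value, best_prob


def extract_all(
    doc: AnnotatedDocument,
    date_model: NaiveBayesModel | None = None,
    count_model: NaiveBayesModel | None = None,
    geo_first_k: int = 3,
) -> KeyExtractionResult:
    """Extract the key disease, country, date and count from one article.

    Disease and country use the most-frequent approach (country
    restricted to the first ``geo_first_k`` geographic mentions); date
    and count use the key-sentence classifier when a model is supplied,
    falling back to most-frequent otherwise.
    """
    result = KeyExtractionResult(
        disease=most_frequent_key(doc.mentions, "disease"),
        country=most_frequent_key(doc.mentions, "geo", first_k=geo_first_k),
    )
    for entity_class, model in (("date", date_model), ("count", count_model)):
        if model is not None:
            picked = select_key_entity(model, doc, entity_class)
            value, prob = picked if picked is not None else (None, None)
        else:
            value, prob = most_frequent_key(doc.mentions, entity_class), None
        if entity_class == "date":
            result.date, result.date_probability = value, prob
        else:
            result.count, result.count_probability = value, prob
    return result


def save_model(model: NaiveBayesModel, path: str | Path) -> None:
    """Serialise a naive Bayes model to a single JSON file."""
    payload = {
        "variant": model.variant,
        "vocabulary": list(model.vocabulary.terms),
        "log_prior": model.log_prior,
        "feature_params": {k: v.tolist() for k, v in model.feature_params.items()},
        "smoothing": model.smoothing,
        "idf": None if model.idf is None else model.idf.tolist(),
        "n_documents": model.n_documents,
    }
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle)


def load_model(path: str | Path) -> NaiveBayesModel:
    with open(path, encoding="utf-8") as handle:
        payload = json.load(handle)
    terms = tuple(payload["vocabulary"])
    return NaiveBayesModel(
        variant=payload["variant"],
        vocabulary=Vocabulary(terms=terms, index={t: i for i, t in enumerate(terms)}),
        log_prior=payload["log_prior"],
        feature_params={k: np.array(v) for k, v in payload["feature_params"].items()},
        smoothing=payload["smoothing"],
        idf=None if payload["idf"] is None else np.array(payload["idf"]),
        n_documents=payload["n_documents"],
    )
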