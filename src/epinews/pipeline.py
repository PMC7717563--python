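"""End-to-end composition: annotate → extract key facts → score relevance.

These functions wire the stage modules together the way the CLI and the
examples use them; each stage remains independently usable.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .annotate import AnnotatedDocument, Gazetteer, annotate
from .corpus import AnalysisRecord, Article, GoldRecord
from .features import (
    EmbeddingModel,
    Vocabulary,
    build_vocabulary,
    count_vector,
    document_embedding,
    tokenize,
    train_embeddings,
)
from .keyinfo import (
    NaiveBayesModel,
    build_sentence_dataset,
    extract_all,
    fit_naive_bayes,
)
from .relevance import LabeledVector, RelevanceModel, score

__all__ = [
    "annotate_corpus",
    "train_key_models",
    "embedding_dataset",
    "bow_dataset",
    "analyze_corpus",
]


def annotate_corpus(
    articles: Sequence[Article],
    disease_gazetteer: Gazetteer | None = None,
    geo_gazetteer: Gazetteer | None = None,
) -> list[AnnotatedDocument]:
    return [annotate(a, disease_gazetteer, geo_gazetteer) for a in articles]


def train_key_models(
    docs: Sequence[AnnotatedDocument],
    gold: Sequence[GoldRecord],
    variant: str = "bernoulli",
    date_window_days: int = 3,
) -> tuple[NaiveBayesModel, NaiveBayesModel]:
    """One key-sentence model per class (date, count)."""
    date_examples = build_sentence_dataset(docs, gold, "date", date_window_days)
    count_examples = build_sentence_dataset(docs, gold, "count", date_window_days)
    return (
        fit_naive_bayes(date_examples, variant),
        fit_naive_bayes(count_examples, variant),
    )


def embedding_dataset(
    articles: Sequence[Article],
    gold: Sequence[GoldRecord],
    embeddings: EmbeddingModel,
) -> list[LabeledVector]:
    """Mean-pooled document embeddings labeled relevant/irrelevant."""
    labels = {g.article_id: g.relevant for g in gold}
    return [
        LabeledVector(
            article_id=a.id,
            features=document_embedding(tokenize(a.text), embeddings),
            label="relevant" if labels[a.id] else "irrelevant",
        )
        for a in articles
    ]


def bow_dataset(
    articles: Sequence[Article],
    gold: Sequence[GoldRecord],
    vocabulary: Vocabulary | None = None,
) -> tuple[list[LabeledVector], Vocabulary]:
    """Count bag-of-words vectors labeled relevant/irrelevant."""
    token_lists = [tokenize(a.text) for a in articles]
    if vocabulary is None:
        vocabulary = build_vocabulary(token_lists)
    labels = {g.article_id: g.relevant for g in gold}
    dataset = [
        LabeledVector(
            article_id=a.id,
            features=count_vector(tokens, vocabulary),
            label="relevant" if labels[a.id] else "irrelevant",
        )
        for a, tokens in zip(articles, token_lists)
    ]
    return dataset, vocabulary


def analyze_corpus(
    docs: Sequence[AnnotatedDocument],
    date_model: NaiveBayesModel | None = None,
    count_model: NaiveBayesModel | None = None,
    relevance_model: RelevanceModel | None = None,
    embeddings: EmbeddingModel | None = None,
) -> list[AnalysisRecord]:
    """One analysis row per article: key disease/country by the
    most-frequent approach, key date/count by the sentence classifier,
    and a relevance score (0 when no relevance model is supplied —
    scores sort the reading list, they never filter it)."""
    records = []
    for doc in docs:
        result = extract_all(doc, date_model, count_model)
        relevance = 0.0
        if relevance_model is not None and embeddings is not None:
            features = document_embedding(tokenize(doc.article.text), embeddings)
            relevance = score(relevance_model, features)
        records.append(
            AnalysisRecord(
                article_id=doc.article.id,
                source=doc.article.source,
                url=doc.article.url,
                disease=result.disease,
                country=result.country,
                date=result.date,
                confirmed_case_count=result.count,
                date_confidence=result.date_probability,
                count_confidence=result.count_probability,
                relevance_score=relevance,
            )
        )
    return records
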