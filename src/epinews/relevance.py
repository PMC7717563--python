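"""Relevance classification of outbreak articles.

An article is *relevant* when its event belongs in the incident
database — a rare outcome (about 5% of articles), so everything here
is built around class imbalance: stratified splitting, minority
up-sampling by convex interpolation, and metrics that respect the
minority class (see :mod:`epinews.metrics`).

The up-sampler implements a literal three-step procedure: repeatedly
(1) pick a random minority point ``x_i``, (2) pick ``x_z`` uniformly
among its 5 nearest minority neighbours (Euclidean), (3) emit
``y = a * x_i + (1 - a) * x_z`` with ``a ~ Uniform(0, 1)``, until the
minority reaches the desired proportion of the majority (1:1 by
default).  Note this selects ``x_i`` uniformly — it does not apply the
density-weighted selection of canonical ADASYN — and consequently never
leaves the convex hull of the minority class.

Classifier fitting delegates to scikit-learn with ecosystem-default
hyperparameters; the feature-mode contract is enforced here: the naive
Bayes variants consume bag-of-words vectors, everything else consumes
document embeddings.  Up-sampling is applied to training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import ComplementNB, MultinomialNB
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .features import BowVector

__all__ = [
    "LabeledVector",
    "SplitSpec",
    "RelevanceModel",
    "ALGORITHMS",
    "stratified_split",
    "three_way_split",
    "adasyn_upsample",
    "fit_relevance",
    "score",
    "score_many",
    "rank_articles",
]

Algorithm = Literal[
    "multinomial_nb", "complement_nb", "logistic_regression", "knn", "svm", "mlp"
]

#: algorithm name -> required feature mode
ALGORITHMS: dict[str, str] = {
    "multinomial_nb": "bow",
    "complement_nb": "bow",
    "logistic_regression": "embedding",
    "knn": "embedding",
    "svm": "embedding",
    "mlp": "embedding",
}


@dataclass(frozen=True)
class LabeledVector:
    """One article's feature vector with its relevance label."""

    article_id: str
    features: np.ndarray | BowVector
    label: Literal["relevant", "irrelevant"]

    def dense(self) -> np.ndarray:
        if isinstance(self.features, BowVector):
            return self.features.values
        return self.features


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.25
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie strictly between 0 and 1")


def _check_min_class_size(labels: Sequence[str], minimum: int = 2) -> None:
    unique, counts = np.unique(np.asarray(labels), return_counts=True)
    for cls, n in zip(unique, counts):
        if n < minimum:
            raise ValueError(f"class {cls!r} has only {n} member(s); need >= {minimum}")


def stratified_split(
    dataset: Sequence[LabeledVector], spec: SplitSpec = SplitSpec()
) -> tuple[list[LabeledVector], list[LabeledVector]]:
    """Deterministic stratified partition into train and test."""
    labels = [d.label for d in dataset]
    _check_min_class_size(labels)
    train, test = train_test_split(
        list(dataset),
        test_size=spec.test_fraction,
        stratify=labels if spec.stratified else None,
        random_state=spec.seed,
    )
    return train, test


def three_way_split(
    dataset: Sequence[LabeledVector],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[list[LabeledVector], list[LabeledVector], list[LabeledVector]]:
    """Stratified train/validation/test partition."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    labels = [d.label for d in dataset]
    _check_min_class_size(labels)
    train, rest = train_test_split(
        list(dataset), test_size=fractions[1] + fractions[2],
        stratify=labels, random_state=seed,
    )
    rest_labels = [d.label for d in rest]
    val, test = train_test_split(
        rest, test_size=fractions[2] / (fractions[1] + fractions[2]),
        stratify=rest_labels, random_state=seed,
    )
    return train, val, test


def adasyn_upsample(
    minority: np.ndarray,
    majority: np.ndarray,
    k: int = 5,
    target_ratio: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Generate synthetic minority points by convex interpolation.

    Returns an ``(m, d)`` array of new points such that
    ``len(minority) + m >= target_ratio * len(majority)``.  Each point
    lies on the segment between a minority point and one of its ``k``
    nearest minority neighbours, so the output never leaves the convex
    hull of the minority class.
    """
    minority = np.asarray(minority, dtype=float)
    majority = np.asarray(majority, dtype=float)
    if len(minority) < 2:
        raise ValueError("up-sampling needs at least 2 minority points")
    n_needed = int(np.ceil(target_ratio * len(majority))) - len(minority)
    if n_needed <= 0:
        return np.empty((0, minority.shape[1]))
    k_eff = min(k, len(minority) - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(minority)
    # column 0 is the point itself
    neighbor_ids = nn.kneighbors(minority, return_distance=False)[:, 1:]
    rng = np.random.default_rng(seed)
    synthetic = np.empty((n_needed, minority.shape[1]))
    for j in range(n_needed):
        i = rng.integers(len(minority))
        z = neighbor_ids[i][rng.integers(k_eff)]
        a = rng.uniform()
        synthetic[j] = a * minority[i] + (1.0 - a) * minority[z]
    return synthetic


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "multinomial_nb":
        return MultinomialNB()
    if algorithm == "complement_nb":
        return ComplementNB()
    if algorithm == "logistic_regression":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if algorithm == "knn":
        return KNeighborsClassifier()
    if algorithm == "svm":
        return SVC(probability=True, random_state=seed)
    if algorithm == "mlp":
        return MLPClassifier(random_state=seed, max_iter=500)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}")


@dataclass
class RelevanceModel:
    """A fitted relevance classifier: algorithm name, feature mode and
    the underlying scikit-learn estimator (class order fixed so the
    positive column is always 'relevant')."""

    algorithm: str
    feature_mode: str
    estimator: object
    positive_index: int


def fit_relevance(
    train: Sequence[LabeledVector],
    algorithm: Algorithm = "logistic_regression",
    seed: int = 0,
    upsample: bool = True,
    adasyn_k: int = 5,
    target_ratio: float = 1.0,
) -> RelevanceModel:
    """Fit a relevance classifier on training vectors.

    Enforces the feature-mode pairing (naive Bayes variants: bag-of-words;
    the rest: document embeddings).  When ``upsample`` is set, the
    minority class of the *training* vectors is up-sampled to
    ``target_ratio`` times the majority before fitting; test data must
    never pass through here.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}")
    required = ALGORITHMS[algorithm]
    for item in train:
        is_bow = isinstance(item.features, BowVector)
        if required == "bow" and not is_bow:
            raise ValueError(f"{algorithm} requires bag-of-words features")
        if required == "embedding" and is_bow:
            raise ValueError(f"{algorithm} requires document-embedding features")

    labels = [d.label for d in train]
    _check_min_class_size(labels)
    x = np.stack([d.dense() for d in train])
    y = np.array(labels)

    if upsample:
        counts = {lbl: int((y == lbl).sum()) for lbl in ("relevant", "irrelevant")}
        minority_label = min(counts, key=counts.get)
        majority_label = max(counts, key=counts.get)
        if counts[minority_label] < counts[majority_label]:
            synthetic = adasyn_upsample(
                x[y == minority_label], x[y == majority_label],
                k=adasyn_k, target_ratio=target_ratio, seed=seed,
            )
            if required == "bow":
                synthetic = np.maximum(synthetic, 0.0)
            if len(synthetic):
                x = np.vstack([x, synthetic])
                y = np.concatenate([y, np.full(len(synthetic), minority_label)])

    estimator = _make_estimator(algorithm, seed)
    estimator.fit(x, y)
    positive_index = list(estimator.classes_).index("relevant")
    return RelevanceModel(
        algorithm=algorithm, feature_mode=required,
        estimator=estimator, positive_index=positive_index,
    )


def score_many(model: RelevanceModel, features: np.ndarray) -> np.ndarray:
    """Probabilities of 'relevant' for a stack of feature vectors."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    return model.estimator.predict_proba(features)[:, model.positive_index]


def score(model: RelevanceModel, features: np.ndarray | BowVector) -> float:
    """Probability of 'relevant' for one feature vector.  The class
    decision is ``score >= 0.5`` (the decision boundary is not tuned)."""
    vector = features.values if isinstance(features, BowVector) else features
    return float(score_many(model, vector)[0])


def rank_articles(scored: Sequence[tuple[str, float]]) -> list[tuple[str, float]]:
    """Stable descending sort by score; ties preserve input order.
    Scores order the reading list — they never drop articles."""
    return sorted(scored, key=lambda pair: -pair[1])
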