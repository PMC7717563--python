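"""Synthetic outbreak-news corpus generator with full ground truth.

Emulates the structure that makes key-entity extraction hard in real
outbreak news: the database-worthy facts live in one *key* sentence,
surrounded by distractor sentences carrying other countries, other
dates and other case counts.  Two features are deliberate:

* the article's publication date and a cumulative regional total each
  appear **twice**, so the most-frequent heuristic picks them — and is
  therefore wrong for date and count, as observed on real news — while
  the key sentence's distinctive wording lets a sentence classifier
  find the right value;
* the relevance label is a known deterministic rule — the article is
  relevant iff its disease belongs to a priority list AND its confirmed
  count reaches a threshold — optionally flipped with probability
  ``label_noise``.  The count half of the rule is hard to read off a
  document embedding, so relevance is learnable but not perfectly so,
  mimicking a weak real-world signal.  Exactly
  ``round(n_articles * relevant_fraction)`` articles satisfy the rule,
  giving exact, controllable class imbalance (default 5% relevant).

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from datetime import timedelta
from typing import Sequence

import numpy as np

from .annotate import bundled_gazetteer, split_sentences
from .corpus import Article, GoldRecord

__all__ = ["GeneratorConfig", "SyntheticCorpus", "generate", "corrupt"]

_MONTH_NAMES = ["January", "February", "March", "April", "May", "June", "July",
                "August", "September", "October", "November", "December"]

#: diseases whose outbreaks are always database-worthy at scale
PRIORITY_DISEASES = (
    "Ebola virus disease",
    "Cholera",
    "Lassa fever",
    "Nipah virus infection",
    "Plague",
    "Yellow fever",
    "Middle East respiratory syndrome",
    "Marburg virus disease",
)

KEY_TEMPLATE = (
    "As of {date}, {count} cases of {disease} have been confirmed in {country}."
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_articles: int = 100
    relevant_fraction: float = 0.05
    n_distractors: tuple[int, int] = (3, 6)
    date_start: Date = Date(2018, 1, 1)
    date_end: Date = Date(2018, 12, 31)
    count_range: tuple[int, int] = (5, 2000)
    count_threshold: int = 100  # relevance rule: count >= threshold
    label_noise: float = 0.0
    key_template: str = KEY_TEMPLATE
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.relevant_fraction < 1.0:
            raise ValueError("relevant_fraction must lie strictly between 0 and 1")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if self.n_articles < 1:
            raise ValueError("n_articles must be positive")
        if self.count_range[0] >= self.count_range[1]:
            raise ValueError("count_range must be an increasing pair")


@dataclass
class SyntheticCorpus:
    """Articles plus gold records plus provenance (which sentence index
    holds the key facts of each article)."""

    articles: list[Article]
    gold: list[GoldRecord]
    provenance: dict[str, int]


def _format_date(d: Date, iso: bool) -> str:
    if iso:
        return d.isoformat()
    return f"{d.day} {_MONTH_NAMES[d.month - 1]} {d.year}"


def _random_date(rng: np.random.Generator, start: Date, end: Date) -> Date:
    return start + timedelta(days=int(rng.integers((end - start).days + 1)))


def generate(config: GeneratorConfig = GeneratorConfig()) -> SyntheticCorpus:
    """Generate a corpus with ground truth; see the module docstring for
    the construction."""
    rng = np.random.default_rng(config.seed)
    diseases = sorted(set(bundled_gazetteer("disease").entries.values()))
    countries = sorted(set(bundled_gazetteer("geo").entries.values()))
    priority = [d for d in PRIORITY_DISEASES if d in diseases]
    non_priority = [d for d in diseases if d not in priority]

    n = config.n_articles
    n_relevant = round(n * config.relevant_fraction)
    relevant_ids = set(rng.choice(n, size=n_relevant, replace=False).tolist())

    articles: list[Article] = []
    gold: list[GoldRecord] = []
    provenance: dict[str, int] = {}
    lo, hi = config.count_range

    for i in range(n):
        rule_relevant = i in relevant_ids
        if rule_relevant:
            disease = priority[rng.integers(len(priority))]
            count = int(rng.integers(config.count_threshold, hi + 1))
        elif rng.uniform() < 0.3 and lo < config.count_threshold:
            # a priority disease with a sub-threshold count: irrelevant
            disease = priority[rng.integers(len(priority))]
            count = int(rng.integers(lo, config.count_threshold))
        else:
            disease = non_priority[rng.integers(len(non_priority))]
            count = int(rng.integers(lo, hi + 1))
        country = countries[rng.integers(len(countries))]
        key_date = _random_date(rng, config.date_start, config.date_end)

        # publication date: > 3 days from the key date, repeated twice
        shift = int(rng.integers(7, 61)) * (1 if rng.uniform() < 0.5 else -1)
        pub_date = key_date + timedelta(days=shift)
        # cumulative total != key count, repeated twice
        total = count
        while total == count:
            total = int(rng.integers(lo, 3 * hi))
        other_count = count
        while other_count in (count, total):
            other_count = int(rng.integers(lo, hi + 1))
        others = [c for c in countries if c != country]
        other_countries = [others[j] for j in rng.choice(len(others), 3, replace=False)]
        other_disease = diseases[rng.integers(len(diseases))]
        while other_disease == disease:
            other_disease = diseases[rng.integers(len(diseases))]

        key_sentence = config.key_template.format(
            date=_format_date(key_date, iso=bool(rng.uniform() < 0.5)),
            count=count, disease=disease, country=country,
        )
        intro = f"An outbreak of {disease} is ongoing in {country}."
        distractor_pool = [
            f"This bulletin was published on {_format_date(pub_date, iso=False)}.",
            f"The previous update of {_format_date(pub_date, iso=False)} summarised "
            f"the regional situation.",
            f"A total of {total} cases have been reported in the region since the "
            f"start of the epidemic.",
            f"Regional health authorities previously mentioned {total} cases in "
            f"earlier bulletins.",
            f"The ministry of health in {other_countries[0]} reported {other_count} "
            f"suspected cases earlier this year.",
            f"Neighbouring {other_countries[1]} has strengthened screening at border "
            f"crossings.",
            f"Laboratory capacity for {other_disease} testing remains limited in "
            f"{other_countries[2]}.",
            "Surveillance activities and community engagement continue across the "
            "affected districts.",
            "Vaccination campaigns and risk communication are being scaled up by "
            "partners.",
        ]
        n_distract = int(rng.integers(config.n_distractors[0], config.n_distractors[1] + 1))
        chosen = [distractor_pool[j]
                  for j in rng.choice(len(distractor_pool), n_distract, replace=False)]
        body = chosen + [key_sentence]
        order = rng.permutation(len(body))
        sentences = [intro] + [body[j] for j in order]
        key_index = 1 + int(np.where(order == len(body) - 1)[0][0])

        label = rule_relevant
        if config.label_noise > 0 and rng.uniform() < config.label_noise:
            label = not label

        article_id = f"synth-{i:05d}"
        articles.append(
            Article(id=article_id, text=" ".join(sentences), source="synthetic",
                    published=pub_date)
        )
        gold.append(
            GoldRecord(article_id=article_id, disease=disease, country=country,
                       date=key_date, confirmed_case_count=count, relevant=label)
        )
        provenance[article_id] = key_index
    return SyntheticCorpus(articles=articles, gold=gold, provenance=provenance)


def corrupt(
    corpus: SyntheticCorpus,
    missing_key_prob: float = 0.0,
    ocr_noise_prob: float = 0.0,
    seed: int = 0,
) -> SyntheticCorpus:
    """Stress fixture: drop key sentences and/or perturb characters.

    Gold records stay intact, so degradation curves (accuracy vs damage)
    can be computed.  With both probabilities zero this is the identity.
    """
    if missing_key_prob == 0.0 and ocr_noise_prob == 0.0:
        return SyntheticCorpus(
            articles=list(corpus.articles), gold=list(corpus.gold),
            provenance=dict(corpus.provenance),
        )
    rng = np.random.default_rng(seed)
    letters = "abcdefghijklmnopqrstuvwxyz"
    articles: list[Article] = []
    provenance: dict[str, int] = {}
    for article in corpus.articles:
        key_index = corpus.provenance.get(article.id, -1)
        spans = split_sentences(article.text)
        keep = list(range(len(spans)))
        if key_index >= 0 and rng.uniform() < missing_key_prob:
            keep.remove(key_index)
            key_index = -1
        text = " ".join(article.text[s:e] for s, e in
                        (spans[j] for j in keep))
        if ocr_noise_prob > 0.0:
            chars = list(text)
            for pos, ch in enumerate(chars):
                if ch.isalpha() and rng.uniform() < ocr_noise_prob:
                    chars[pos] = letters[rng.integers(26)]
            text = "".join(chars)
        articles.append(Article(id=article.id, text=text, source=article.source,
                                url=article.url, published=article.published))
        provenance[article.id] = key_index
    return SyntheticCorpus(articles=articles, gold=list(corpus.gold),
                           provenance=provenance)
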