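"""Article and gold-record data model with JSONL / CSV readers and writers.

An event-based-surveillance corpus is a JSON-lines file, one article per
line, paired with a CSV "incident database" holding the single gold
disease, country, date, confirmed-case count and relevance label per
article.  Analysis output (the extracted key facts plus a relevance
score) is written back as CSV.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Article",
    "GoldRecord",
    "AnalysisRecord",
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
    "read_gold",
    "write_gold",
    "write_analysis",
]


class CorpusFormatError(ValueError):
    """Raised when a corpus or gold file violates the format contract."""


@dataclass(frozen=True)
class Article:
    """One outbreak-news article.

    ``id`` must be unique within a corpus and ``text`` non-empty.
    ``published`` is the publication date when known; ``source`` names
    the feed the article came from (e.g. ``"WHO DON"``, ``"ProMED"``,
    ``"synthetic"``).
    """

    id: str
    text: str
    source: str = "unknown"
    url: str | None = None
    published: Date | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("article id must be non-empty")
        if not self.text:
            raise ValueError(f"article {self.id!r}: text must be non-empty")


@dataclass(frozen=True)
class GoldRecord:
    """Gold key facts for one article: the single disease, country, date
    and confirmed-case count that characterise the event, plus whether
    the article was judged relevant."""

    article_id: str
    disease: str
    country: str
    date: Date
    confirmed_case_count: int
    relevant: bool

    def __post_init__(self) -> None:
        if self.confirmed_case_count < 0:
            raise ValueError(
                f"gold record {self.article_id!r}: confirmed_case_count must be >= 0"
            )


@dataclass
class AnalysisRecord:
    """Extracted key facts and relevance score for one article.

    Every extracted field is optional (an article may lack a disease
    mention, say); ``*_confidence`` fields hold the key-sentence
    posterior where a classifier produced the value.
    """

    article_id: str
    source: str = "unknown"
    url: str | None = None
    disease: str | None = None
    country: str | None = None
    date: Date | None = None
    confirmed_case_count: int | None = None
    date_confidence: float | None = None
    count_confidence: float | None = None
    relevance_score: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.relevance_score <= 1.0:
            raise ValueError("relevance_score must lie in [0, 1]")
        for name in ("date_confidence", "count_confidence"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def _article_to_json(article: Article) -> dict:
    record: dict = {"id": article.id, "source": article.source, "text": article.text}
    if article.url is not None:
        record["url"] = article.url
    if article.published is not None:
        record["published"] = article.published.isoformat()
    return record


def _article_from_json(obj: dict, lineno: int) -> Article:
    try:
        published = obj.get("published")
        return Article(
            id=str(obj["id"]),
            text=obj["text"],
            source=obj.get("source", "unknown"),
            url=obj.get("url"),
            published=Date.fromisoformat(published) if published else None,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise CorpusFormatError(f"line {lineno}: malformed article record: {exc}") from exc


def read_corpus(path: str | Path) -> list[Article]:
    """Read a JSONL corpus, preserving file order and checking id uniqueness."""
    articles: list[Article] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON: {exc}") from exc
            article = _article_from_json(obj, lineno)
            if article.id in seen:
                raise CorpusFormatError(f"line {lineno}: duplicate article id {article.id!r}")
            seen.add(article.id)
            articles.append(article)
    return articles


def write_corpus(articles: Iterable[Article], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for article in articles:
            handle.write(json.dumps(_article_to_json(article), ensure_ascii=False))
            handle.write("\n")


_GOLD_COLUMNS = ["article_id", "disease", "country", "date", "confirmed_case_count", "relevant"]


def read_gold(path: str | Path) -> list[GoldRecord]:
    """Read the gold CSV; rejects negative counts and unparseable dates,
    naming the offending row."""
    records: list[GoldRecord] = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle)
        for rowno, row in enumerate(reader, start=2):  # row 1 is the header
            try:
                count = int(row["confirmed_case_count"])
                record = GoldRecord(
                    article_id=row["article_id"],
                    disease=row["disease"],
                    country=row["country"],
                    date=Date.fromisoformat(row["date"]),
                    confirmed_case_count=count,
                    relevant=row["relevant"].strip().lower() in {"1", "true", "yes"},
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise CorpusFormatError(f"row {rowno}: invalid gold record: {exc}") from exc
            records.append(record)
    return records


def write_gold(records: Iterable[GoldRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(_GOLD_COLUMNS)
        for r in records:
            writer.writerow(
                [r.article_id, r.disease, r.country, r.date.isoformat(),
                 r.confirmed_case_count, str(r.relevant).lower()]
            )


_ANALYSIS_COLUMNS = [
    "article_id", "source", "url", "disease", "country", "date",
    "confirmed_case_count", "relevance_score",
]


def write_analysis(records: Sequence[AnalysisRecord], path: str | Path) -> None:
    """Write analysis rows (ISO 8601 dates, UTF-8, header always present)."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(_ANALYSIS_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.article_id,
                    r.source,
                    r.url or "",
                    r.disease or "",
                    r.country or "",
                    r.date.isoformat() if r.date else "",
                    "" if r.confirmed_case_count is None else r.confirmed_case_count,
                    f"{r.relevance_score:.6f}",
                ]
            )
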