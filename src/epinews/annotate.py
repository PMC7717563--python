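"""Sentence segmentation and rule-based epidemiological NER.

Produces the four entity classes the extraction pipeline consumes —
``disease``, ``geo``, ``date`` and ``count`` — from plain text, using
gazetteers for diseases and places and regular expressions for dates
and counts.  The annotator is deliberately a small, deterministic,
pluggable component: downstream code depends only on the
:class:`EntityMention` contract, not on how mentions were found.

Matching rules
--------------
* Gazetteer matches are case-insensitive, word-boundary anchored and
  longest-match; overlapping candidates within a class are resolved
  leftmost-longest.
* Date expressions cover ISO dates (``2018-05-10``), ``10 May 2018``
  and ``May 10, 2018`` (year-less forms resolve against a reference
  date); a range such as ``2018-05-10 to 2018-05-12`` collapses to a
  single mention valued at the range midpoint.
* Counts are digit groups with optional thousands separators; digits
  already consumed by a date never become counts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from datetime import date as Date
from datetime import timedelta
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence, Union

from .corpus import Article

__all__ = [
    "Gazetteer",
    "EntityMention",
    "AnnotatedDocument",
    "split_sentences",
    "annotate_gazetteer",
    "annotate_dates",
    "annotate_counts",
    "annotate",
    "load_gazetteer",
    "bundled_gazetteer",
]

logger = logging.getLogger(__name__)

EntityClass = Literal["disease", "geo", "date", "count"]
MentionValue = Union[str, Date, int]


@dataclass(frozen=True)
class EntityMention:
    """One recognised entity: class, character span (0-based, half-open),
    surface string, sentence index and normalised value (canonical name
    for disease/geo, a calendar date, or a non-negative integer)."""

    entity_class: EntityClass
    surface: str
    start: int
    end: int
    value: MentionValue
    sentence_index: int = -1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


class Gazetteer:
    """Case-insensitive surface-form → canonical-name lookup for one
    entity class (``disease`` or ``geo``)."""

    def __init__(self, entries: dict[str, str], entity_class: EntityClass):
        if entity_class not in ("disease", "geo"):
            raise ValueError("gazetteer entity_class must be 'disease' or 'geo'")
        cleaned = {}
        for surface, canonical in entries.items():
            if not surface.strip():
                raise ValueError("gazetteer surface forms must be non-empty")
            cleaned[surface.strip().lower()] = canonical
        if not cleaned:
            raise ValueError("gazetteer must have at least one entry")
        self.entries = cleaned
        self.entity_class: EntityClass = entity_class
        # Alternation ordered longest-first => regex engine yields the
        # longest candidate at each position; scanning is leftmost.
        alternation = "|".join(
            re.escape(s) for s in sorted(self.entries, key=len, reverse=True)
        )
        self._pattern = re.compile(rf"(?<!\w)(?:{alternation})(?!\w)", re.IGNORECASE)

    def __len__(self) -> int:
        return len(self.entries)


def load_gazetteer(path: str | Path, entity_class: EntityClass) -> Gazetteer:
    """Load a two-column TSV (surface_form<TAB>canonical_name)."""
    entries: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}, line {lineno}: expected 2 tab-separated columns")
            entries[parts[0]] = parts[1]
    return Gazetteer(entries, entity_class)


def bundled_gazetteer(entity_class: EntityClass) -> Gazetteer:
    """The gazetteer shipped with the package (countries or diseases)."""
    name = {"geo": "countries.tsv", "disease": "diseases.tsv"}[entity_class]
    path = resources.files("epinews.data") / name
    return load_gazetteer(str(path), entity_class)


@dataclass
class AnnotatedDocument:
    """An article plus its sentence spans and all entity mentions.

    Sentence spans are disjoint and ordered; every mention lies inside
    exactly one sentence (``sentence_index``)."""

    article: Article
    sentences: list[tuple[tuple[int, int], str]]
    mentions: list[EntityMention]

    def mentions_of(self, entity_class: EntityClass) -> list[EntityMention]:
        return [m for m in self.mentions if m.entity_class == entity_class]

    def sentence_tokens_text(self, index: int) -> str:
        return self.sentences[index][1]


_SENTENCE_BOUNDARY = re.compile(r"[.!?]+(?=\s|$)")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Split text into sentence spans at terminal punctuation.

    Returns (start, end) character spans, 0-based half-open, whose
    concatenation (plus the whitespace between them) reconstructs the
    text.  Whitespace-only text yields no spans; text without terminal
    punctuation is a single sentence.
    """
    spans: list[tuple[int, int]] = []
    cursor = 0
    for match in _SENTENCE_BOUNDARY.finditer(text):
        end = match.end()
        segment = text[cursor:end]
        stripped = segment.strip()
        if stripped:
            start = cursor + (len(segment) - len(segment.lstrip()))
            spans.append((start, start + len(stripped)))
        cursor = end
    tail = text[cursor:]
    if tail.strip():
        start = cursor + (len(tail) - len(tail.lstrip()))
        spans.append((start, start + len(tail.strip())))
    return spans


def annotate_gazetteer(text: str, gazetteer: Gazetteer) -> list[EntityMention]:
    """Find all gazetteer matches (leftmost-longest, non-overlapping)."""
    mentions = []
    for match in gazetteer._pattern.finditer(text):
        surface = match.group(0)
        mentions.append(
            EntityMention(
                entity_class=gazetteer.entity_class,
                surface=surface,
                start=match.start(),
                end=match.end(),
                value=gazetteer.entries[surface.lower()],
            )
        )
    return mentions


_MONTHS = {
    name.lower(): i + 1
    for i, name in enumerate(
        ["January", "February", "March", "April", "May", "June", "July",
         "August", "September", "October", "November", "December"]
    )
}
_MONTHS.update({name[:3]: num for name, num in list(_MONTHS.items())})
_MONTH_RE = "|".join(sorted(_MONTHS, key=len, reverse=True))

# Order matters: ISO first, then day-month-year, then month-day-year.
_DATE_PATTERNS = [
    re.compile(r"\b(?P<y>\d{4})-(?P<m>\d{2})-(?P<d>\d{2})\b"),
    re.compile(
        rf"\b(?P<d>\d{{1,2}})(?:st|nd|rd|th)?\s+(?P<mon>{_MONTH_RE})\.?(?:\s+(?P<y>\d{{4}}))?\b",
        re.IGNORECASE,
    ),
    re.compile(
        rf"\b(?P<mon>{_MONTH_RE})\.?\s+(?P<d>\d{{1,2}})(?:st|nd|rd|th)?(?:,?\s+(?P<y>\d{{4}}))?\b",
        re.IGNORECASE,
    ),
]

_RANGE_CONNECTOR = re.compile(r"\s*(?:to|until|through|–|—|-)\s*")


def _resolve_date(match: re.Match, reference_date: Date) -> Date | None:
    groups = match.groupdict()
    try:
        year = int(groups["y"]) if groups.get("y") else reference_date.year
        month = _MONTHS[groups["mon"].lower()] if groups.get("mon") else int(groups["m"])
        return Date(year, month, int(groups["d"]))
    except (KeyError, ValueError):
        logger.debug("skipping unparseable date candidate %r", match.group(0))
        return None


def annotate_dates(text: str, reference_date: Date | None = None) -> list[EntityMention]:
    """Find date mentions; ranges collapse to their midpoint date."""
    reference_date = reference_date or Date.today()
    raw: list[tuple[int, int, Date, str]] = []
    claimed: list[tuple[int, int]] = []
    for pattern in _DATE_PATTERNS:
        for match in pattern.finditer(text):
            if any(match.start() < e and s < match.end() for s, e in claimed):
                continue
            value = _resolve_date(match, reference_date)
            if value is None:
                continue
            claimed.append((match.start(), match.end()))
            raw.append((match.start(), match.end(), value, match.group(0)))
    raw.sort()

    # Merge "A to B" pairs into one midpoint-valued mention.
    mentions: list[EntityMention] = []
    i = 0
    while i < len(raw):
        start, end, value, _ = raw[i]
        if i + 1 < len(raw):
            gap = text[end:raw[i + 1][0]]
            if _RANGE_CONNECTOR.fullmatch(gap):
                n_start, n_end, n_value, _ = raw[i + 1]
                lo, hi = sorted((value, n_value))
                midpoint = lo + timedelta(days=(hi - lo).days // 2)
                mentions.append(
                    EntityMention("date", text[start:n_end], start, n_end, midpoint)
                )
                i += 2
                continue
        mentions.append(EntityMention("date", text[start:end], start, end, value))
        i += 1
    return mentions


_COUNT_PATTERN = re.compile(r"\b\d{1,3}(?:,\d{3})+\b|\b\d+\b")


def annotate_counts(
    text: str, exclude_spans: Iterable[tuple[int, int]] = ()
) -> list[EntityMention]:
    """Find integer count mentions, skipping digits inside ``exclude_spans``
    (typically the spans of already-matched dates)."""
    exclude = list(exclude_spans)
    mentions = []
    for match in _COUNT_PATTERN.finditer(text):
        if any(match.start() < e and s < match.end() for s, e in exclude):
            continue
        value = int(match.group(0).replace(",", ""))
        mentions.append(
            EntityMention("count", match.group(0), match.start(), match.end(), value)
        )
    return mentions


def _assign_sentence_index(
    mention: EntityMention, sentences: Sequence[tuple[int, int]]
) -> EntityMention:
    for index, (start, end) in enumerate(sentences):
        if start <= mention.start < end:
            return EntityMention(
                mention.entity_class, mention.surface, mention.start,
                mention.end, mention.value, sentence_index=index,
            )
    return mention


def annotate(
    article: Article,
    disease_gazetteer: Gazetteer | None = None,
    geo_gazetteer: Gazetteer | None = None,
    reference_date: Date | None = None,
) -> AnnotatedDocument:
    """Annotate an article with sentences and all four mention classes.

    Date mentions take precedence over counts on overlapping digit
    spans (so a year never becomes a case count).  Empty annotation is
    legal: an article with no recognised entities still yields a valid
    document.
    """
    disease_gazetteer = disease_gazetteer or bundled_gazetteer("disease")
    geo_gazetteer = geo_gazetteer or bundled_gazetteer("geo")
    text = article.text
    sentence_spans = split_sentences(text)

    dates = annotate_dates(text, reference_date or article.published)
    mentions = (
        annotate_gazetteer(text, disease_gazetteer)
        + annotate_gazetteer(text, geo_gazetteer)
        + dates
        + annotate_counts(text, exclude_spans=[m.span for m in dates])
    )
    mentions = [_assign_sentence_index(m, sentence_spans) for m in mentions]
    mentions.sort(key=lambda m: (m.start, m.end))
    return AnnotatedDocument(
        article=article,
        sentences=[(span, text[span[0]:span[1]]) for span in sentence_spans],
        mentions=mentions,
    )
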