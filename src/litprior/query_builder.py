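"""Construction (and round-trip parsing) of expanded PubMed query strings.

Grammar: ``(synonyms OR-block) AND (keywords-block) [AND date-block]`` with
every term an exact-phrase field-tagged token — ``[TI]`` for title-only scope,
``[TIAB]`` for title-or-abstract.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from datetime import date
from typing import Optional, Sequence

from .uniprot_resolver import Scope, SynonymSet, SynonymStatus

logger = logging.getLogger(__name__)

_FIELD_TAG = {Scope.TITLE: "[TI]", Scope.TITLE_ABSTRACT: "[TIAB]"}
_TAG_FIELD = {"TI": Scope.TITLE, "TIAB": Scope.TITLE_ABSTRACT}
# Characters with reserved meaning in E-utilities term syntax.
_RESERVED = re.compile(r'[()\[\]{}"*:#&|]')
_TERM_RE = re.compile(r'"([^"]+)"\[(TI|TIAB)\]')
_DATE_RE = re.compile(
    r'\("(\d{4})/(\d{2})/(\d{2})"\[PDAT\] : "(\d{4})/(\d{2})/(\d{2})"\[PDAT\]\)'
)


@dataclass(frozen=True)
class PubMedQuery:
    text: str
    scope: Scope
    synonym_terms: tuple[str, ...]
    keyword_terms: tuple[str, ...]
    date_range: Optional[tuple[date, date]] = None
    all_keywords: bool = False


def sanitize_phrase(phrase: str) -> str:
    """Strip PubMed-reserved characters from a phrase, warning when any found."""
    cleaned = _RESERVED.sub("", phrase)
    cleaned = re.sub(r"\s+", " ", cleaned).strip()
    if cleaned != phrase.strip():
        logger.warning("stripped reserved characters from phrase %r -> %r", phrase, cleaned)
    return cleaned


def build_query(
    syns: SynonymSet,
    keywords: Sequence[str],
    scope: Scope,
    date_range: Optional[tuple[date, date]] = None,
    all_keywords: bool = False,
) -> PubMedQuery:
    """Build the expanded query for one synonym set.

    Synonyms are OR-joined; keywords are OR-joined by default (AND with
    ``all_keywords``); the two blocks are AND-joined and an optional
    publication-date interval is appended.
    """
    if syns.status is not SynonymStatus.OK:
        raise ValueError("build_query requires a resolved synonym set (status OK)")
    kept_kws = [sanitize_phrase(k) for k in keywords]
    if not kept_kws or any(not k for k in kept_kws):
        raise ValueError("keywords must be non-empty phrases")
    terms = tuple(sanitize_phrase(n) for n in syns.names)
    tag = _FIELD_TAG[scope]
    syn_block = "(" + " OR ".join(f'"{t}"{tag}' for t in terms) + ")"
    joiner = " AND " if all_keywords else " OR "
    kw_block = "(" + joiner.join(f'"{k}"{tag}' for k in kept_kws) + ")"
    text = f"{syn_block} AND {kw_block}"
    if date_range is not None:
        start, end = date_range
        text += (
            f' AND ("{start:%Y/%m/%d}"[PDAT] : "{end:%Y/%m/%d}"[PDAT])'
        )
    return PubMedQuery(
        text=text,
        scope=scope,
        synonym_terms=terms,
        keyword_terms=tuple(kept_kws),
        date_range=date_range,
        all_keywords=all_keywords,
    )


def parse_query(text: str) -> PubMedQuery:
    """Recover synonym terms, keyword terms, scope and date range from a built
    query string (the round-trip inverse of :func:`build_query`)."""
    m_date = _DATE_RE.search(text)
    date_range = None
    body = text
    if m_date:
        y1, mo1, d1, y2, mo2, d2 = (int(g) for g in m_date.groups())
        date_range = (date(y1, mo1, d1), date(y2, mo2, d2))
        body = text[: m_date.start()].rstrip()
        if body.endswith("AND"):
            body = body[:-3].rstrip()

    blocks = _split_top_level_and(body)
    if len(blocks) != 2:
        raise ValueError(f"expected two AND-joined blocks, got {len(blocks)}")
    syn_terms = _TERM_RE.findall(blocks[0])
    kw_terms = _TERM_RE.findall(blocks[1])
    if not syn_terms or not kw_terms:
        raise ValueError("query blocks contain no field-tagged terms")
    tags = {t for _, t in syn_terms + kw_terms}
    if len(tags) != 1:
        raise ValueError(f"inconsistent field tags: {tags}")
    scope = _TAG_FIELD[tags.pop()]
    all_keywords = " AND " in blocks[1]
    return PubMedQuery(
        text=text,
        scope=scope,
        synonym_terms=tuple(t for t, _ in syn_terms),
        keyword_terms=tuple(t for t, _ in kw_terms),
        date_range=date_range,
        all_keywords=all_keywords,
    )


def _split_top_level_and(text: str) -> list[str]:
    parts: list[str] = []
    depth = 0
    token = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if depth == 0 and text.startswith(" AND ", i):
            parts.append("".join(token))
            token = []
            i += 5
            continue
        token.append(ch)
        i += 1
    parts.append("".join(token))
    return [p.strip() for p in parts if p.strip()]
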