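"""Evidence validation and category assignment.

Each retrieved record is validated ("False" check): a synonym and a keyword
must co-occur, whole-word and case-insensitive, within the scoped fields
(title only, or title/abstract). Queries are then tiered:

* Category 1 — at least one validated *review* article,
* Category 2 — validated publications but no review,
* Category 3 — no validated publication,
* Category 0 — no synonyms resolvable (isoform accession or unreviewed
  entry); retrieval is skipped entirely, so Total = 0.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from ._text import phrase_in_text
from .pubmed_retrieval import PubMedRecord, ResultSet
from .uniprot_resolver import QueryRow, Scope, SynonymSet, SynonymStatus


class MatchField(enum.Enum):
    TITLE = "TITLE"
    ABSTRACT = "ABSTRACT"


@dataclass(frozen=True)
class MatchResult:
    pmid: str
    matched: bool
    matched_synonym: Optional[str] = None
    matched_keyword: Optional[str] = None
    matched_field: Optional[MatchField] = None

    def __post_init__(self) -> None:
        both = self.matched_synonym is not None and self.matched_keyword is not None
        if self.matched != both:
            raise ValueError("matched iff both synonym and keyword present")


@dataclass(frozen=True)
class CategoryResult:
    query: QueryRow
    total: int
    category: int
    false_count: int
    matching_pmids: tuple[str, ...] = ()
    review_pmids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.false_count + len(self.matching_pmids) != self.total:
            raise ValueError("false_count + matching must equal total")
        if not set(self.review_pmids) <= set(self.matching_pmids):
            raise ValueError("review pmids must be matching pmids")
        if self.category not in (0, 1, 2, 3):
            raise ValueError("category must be in 0..3")


def is_review(r: PubMedRecord) -> bool:
    """True iff any publication type contains the token "review"."""
    return any("review" in pt.lower() for pt in r.publication_types)


def _first_phrase_in(phrases: Sequence[str], text: str) -> Optional[str]:
    for p in phrases:
        if phrase_in_text(p, text):
            return p
    return None


def record_matches(
    r: PubMedRecord,
    syns: SynonymSet,
    keywords: Sequence[str],
    scope: Scope,
    all_keywords: bool = False,
) -> MatchResult:
    """The "False" check for one record.

    TITLE scope inspects the title only; TITLE_ABSTRACT lets synonym and
    keyword each sit anywhere within title or abstract. A record whose scoped
    fields are missing (e.g., no abstract fetched) simply cannot match, which
    is exactly how incomplete PubMed metadata produces False flags.
    """
    if syns.status is not SynonymStatus.OK:
        raise ValueError("record_matches requires status OK")
    if scope is Scope.TITLE:
        fields = [(MatchField.TITLE, r.title)]
    else:
        fields = [(MatchField.TITLE, r.title), (MatchField.ABSTRACT, r.abstract)]
    joined = " \n ".join(text for _, text in fields)

    syn = _first_phrase_in(syns.names, joined)
    if all_keywords:
        kws_found = [k for k in keywords if phrase_in_text(k, joined)]
        kw = kws_found[0] if len(kws_found) == len(list(keywords)) else None
    else:
        kw = _first_phrase_in(keywords, joined)
    if syn is None or kw is None:
        return MatchResult(pmid=r.pmid, matched=False)
    fld = next(
        (mf for mf, text in fields if phrase_in_text(syn, text)), MatchField.TITLE
    )
    return MatchResult(
        pmid=r.pmid, matched=True, matched_synonym=syn, matched_keyword=kw, matched_field=fld
    )


def categorize(
    syns: SynonymSet,
    rs: Optional[ResultSet],
    keywords: Sequence[str],
    scope: Scope,
    all_keywords: bool = False,
) -> CategoryResult:
    """Assign the evidence category for one query.

    When the synonym set is not resolvable the query is Category 0 and no
    retrieval is consulted (total = 0, false_count = 0).
    """
    if syns.status is not SynonymStatus.OK:
        return CategoryResult(query=syns.query, total=0, category=0, false_count=0)
    records = rs.records if rs is not None else ()
    matching: list[str] = []
    reviews: list[str] = []
    for r in records:
        mr = record_matches(r, syns, keywords, scope, all_keywords=all_keywords)
        if mr.matched:
            matching.append(r.pmid)
            if is_review(r):
                reviews.append(r.pmid)
    if reviews:
        category = 1
    elif matching:
        category = 2
    else:
        category = 3
    return CategoryResult(
        query=syns.query,
        total=len(records),
        category=category,
        false_count=len(records) - len(matching),
        matching_pmids=tuple(matching),
        review_pmids=tuple(reviews),
    )
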