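"""PubMed record retrieval: live E-utilities client and offline fixture corpus.

Both backends normalize to :class:`PubMedRecord`. The offline searcher applies
the same whole-word co-occurrence semantics the validator uses, plus any
hidden indexed terms a fixture record declares (``index_extra``) — these model
the real PubMed situation where the search index matches terms that the
fetched title/abstract metadata does not contain, which is what populates the
"False" column downstream.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

from lxml import etree

from ._text import phrase_in_text
from .query_builder import PubMedQuery
from .uniprot_resolver import RetrievalError, Scope

logger = logging.getLogger(__name__)


class PubMedParseError(ValueError):
    """Malformed payload; carries pmid context when available."""


@dataclass(frozen=True)
class PubMedRecord:
    """One publication's metadata as fetched from PubMed (or a fixture)."""

    pmid: str
    title: str
    abstract: str = ""
    year: Optional[int] = None
    authors: tuple[str, ...] = ()
    country: Optional[str] = None
    mesh_terms: tuple[str, ...] = ()
    publication_types: tuple[str, ...] = ()
    journal: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.pmid:
            raise PubMedParseError("record missing pmid")
        if self.year is not None and not (1000 <= self.year <= 2999):
            raise PubMedParseError(f"pmid {self.pmid}: implausible year {self.year}")


@dataclass(frozen=True)
class ResultSet:
    query: PubMedQuery
    records: tuple[PubMedRecord, ...]
    retrieved_at: datetime
    backend_id: str


def _record_from_dict(d: dict) -> PubMedRecord:
    if "pmid" not in d or not d["pmid"]:
        raise PubMedParseError("payload record missing pmid")
    try:
        year = int(d["year"]) if d.get("year") is not None else None
    except (TypeError, ValueError) as exc:
        raise PubMedParseError(f"pmid {d['pmid']}: malformed year") from exc
    return PubMedRecord(
        pmid=str(d["pmid"]),
        title=d.get("title", "") or "",
        abstract=d.get("abstract", "") or "",
        year=year,
        authors=tuple(d.get("authors") or ()),
        country=d.get("country"),
        mesh_terms=tuple(d.get("mesh_terms") or ()),
        publication_types=tuple(d.get("publication_types") or ()),
        journal=d.get("journal"),
    )


def _records_from_xml(raw: str | bytes) -> list[PubMedRecord]:
    try:
        root = etree.fromstring(raw.encode() if isinstance(raw, str) else raw)
    except etree.XMLSyntaxError as exc:
        raise PubMedParseError(f"malformed E-utilities XML: {exc}") from exc
    out = []
    for art in root.iter("PubmedArticle"):
        pmid = art.findtext(".//MedlineCitation/PMID")
        if not pmid:
            raise PubMedParseError("PubmedArticle without PMID")
        title = "".join((art.find(".//ArticleTitle")).itertext()) if art.find(
            ".//ArticleTitle"
        ) is not None else ""
        abstract = " ".join(
            "".join(el.itertext()) for el in art.findall(".//Abstract/AbstractText")
        ).strip()
        year_text = art.findtext(".//JournalIssue/PubDate/Year") or art.findtext(
            ".//ArticleDate/Year"
        )
        authors = []
        for au in art.findall(".//AuthorList/Author"):
            last = au.findtext("LastName")
            init = au.findtext("Initials")
            if last:
                authors.append(f"{last} {init}" if init else last)
        out.append(
            PubMedRecord(
                pmid=pmid,
                title=title.strip(),
                abstract=abstract,
                year=int(year_text) if year_text else None,
                authors=tuple(authors),
                country=art.findtext(".//MedlineJournalInfo/Country"),
                mesh_terms=tuple(
                    el.text
                    for el in art.findall(".//MeshHeadingList/MeshHeading/DescriptorName")
                    if el.text
                ),
                publication_types=tuple(
                    el.text for el in art.findall(".//PublicationTypeList/PublicationType") if el.text
                ),
                journal=art.findtext(".//Journal/Title"),
            )
        )
    return out


def parse_pubmed_payload(raw) -> list[PubMedRecord]:
    """Normalize a backend payload to records.

    Accepts live efetch XML (string/bytes starting with ``<``), a JSON-lines
    block, a single dict, or a sequence of dicts. Missing abstracts map to the
    empty string; absent metadata stays absent, never fabricated.
    """
    if isinstance(raw, dict):
        return [_record_from_dict(raw)]
    if isinstance(raw, (list, tuple)):
        return [_record_from_dict(d) for d in raw]
    if isinstance(raw, bytes):
        raw = raw.decode("utf-8")
    if isinstance(raw, str):
        stripped = raw.lstrip()
        if stripped.startswith("<"):
            return _records_from_xml(raw)
        out = []
        for ln in raw.splitlines():
            if ln.strip():
                try:
                    out.append(_record_from_dict(json.loads(ln)))
                except json.JSONDecodeError as exc:
                    raise PubMedParseError(f"malformed JSON line: {exc}") from exc
        return out
    raise PubMedParseError(f"unsupported payload type {type(raw).__name__}")


def _searchable_text(rec_dict: dict, scope: Scope) -> str:
    parts = [rec_dict.get("title", "") or ""]
    if scope is Scope.TITLE_ABSTRACT:
        parts.append(rec_dict.get("abstract", "") or "")
    # hidden index terms are searchable in either scope, like PubMed's own
    # indexing of terms invisible in the fetched metadata
    parts.extend(rec_dict.get("index_extra") or ())
    return " \n ".join(parts)


def query_hits(rec_dict: dict, q: PubMedQuery) -> bool:
    """Offline search semantics: some synonym term and the keyword block both
    present (whole-word, case-insensitive) in the scoped searchable text."""
    text = _searchable_text(rec_dict, q.scope)
    if not any(phrase_in_text(s, text) for s in q.synonym_terms):
        return False
    if q.all_keywords:
        return all(phrase_in_text(k, text) for k in q.keyword_terms)
    return any(phrase_in_text(k, text) for k in q.keyword_terms)


class OfflinePubMedBackend:
    """Fixture corpus backend: JSON-lines records, deterministic search."""

    backend_id = "pubmed-fixture"

    def __init__(self, source: Path | str | Sequence[dict]):
        if isinstance(source, (str, Path)):
            path = Path(source)
            if path.is_dir():
                path = path / "pubmed.jsonl"
            self._raw = [
                json.loads(ln) for ln in path.read_text().splitlines() if ln.strip()
            ]
        else:
            self._raw = [dict(d) for d in source]

    def search(self, q: PubMedQuery) -> list[dict]:
        return [d for d in self._raw if query_hits(d, q)]


class LivePubMedBackend:
    """NCBI E-utilities client (esearch + efetch) via Biopython's Entrez.

    Rate-limited to ≤3 requests/s without an API key, bounded exponential
    backoff on transport errors, and optional on-disk response caching keyed
    by the query hash so reruns are reproducible against the cache.
    """

    backend_id = "pubmed-eutils"

    def __init__(
        self,
        email: str,
        api_key: Optional[str] = None,
        cache_dir: Optional[Path] = None,
        max_retries: int = 3,
    ):
        from Bio import Entrez

        self._entrez = Entrez
        Entrez.email = email
        if api_key:
            Entrez.api_key = api_key
        self.cache_dir = Path(cache_dir) if cache_dir else None
        if self.cache_dir:
            self.cache_dir.mkdir(parents=True, exist_ok=True)
        self.max_retries = max_retries
        self._min_interval = 0.34 if not api_key else 0.11
        self._last_request = 0.0

    def _throttle(self) -> None:
        wait = self._min_interval - (time.monotonic() - self._last_request)
        if wait > 0:
            time.sleep(wait)
        self._last_request = time.monotonic()

    def _with_retries(self, fn):
        delay = 1.0
        for attempt in range(self.max_retries):
            try:
                self._throttle()
                return fn()
            except OSError as exc:
                if attempt == self.max_retries - 1:
                    raise RetrievalError(f"E-utilities request failed: {exc}") from exc
                time.sleep(delay)
                delay *= 2

    def search(self, q: PubMedQuery) -> list[dict]:
        import hashlib

        key = hashlib.sha256(q.text.encode()).hexdigest()[:24]
        cache_file = self.cache_dir / f"q_{key}.xml" if self.cache_dir else None
        if cache_file and cache_file.exists():
            xml = cache_file.read_bytes()
        else:
            def _esearch():
                with self._entrez.esearch(db="pubmed", term=q.text, retmax=100000) as h:
                    return self._entrez.read(h)

            ids = self._with_retries(_esearch)["IdList"]
            if not ids:
                xml = b"<PubmedArticleSet/>"
            else:
                def _efetch():
                    with self._entrez.efetch(
                        db="pubmed", id=",".join(ids), rettype="xml", retmode="xml"
                    ) as h:
                        return h.read()

                xml = self._with_retries(_efetch)
                if isinstance(xml, str):
                    xml = xml.encode()
            if cache_file is not None:
                cache_file.write_bytes(xml)
        return [
            {
                "pmid": r.pmid,
                "title": r.title,
                "abstract": r.abstract,
                "year": r.year,
                "authors": list(r.authors),
                "country": r.country,
                "mesh_terms": list(r.mesh_terms),
                "publication_types": list(r.publication_types),
                "journal": r.journal,
            }
            for r in _records_from_xml(xml)
        ]


def _sort_key(rec: PubMedRecord):
    # descending year (missing years last), then pmid (numeric-aware)
    year = rec.year if rec.year is not None else -1
    pmid_key = (len(rec.pmid), rec.pmid) if rec.pmid.isdigit() else (99, rec.pmid)
    return (-year, pmid_key)


def fetch_records(q: PubMedQuery, backend) -> ResultSet:
    """Execute a query and return the deduplicated, deterministically ordered
    result set. A zero-hit query yields an empty ResultSet, not an error."""
    raw = backend.search(q)
    seen: set[str] = set()
    records: list[PubMedRecord] = []
    for rec in parse_pubmed_payload(raw):
        if rec.pmid in seen:
            continue
        seen.add(rec.pmid)
        records.append(rec)
    if q.date_range is not None:
        start, end = q.date_range
        kept = []
        for rec in records:
            if rec.year is None:
                logger.warning("pmid %s has no year; excluded by date filter", rec.pmid)
                continue
            if start.year <= rec.year <= end.year:
                kept.append(rec)
        records = kept
    records.sort(key=_sort_key)
    return ResultSet(
        query=q,
        records=tuple(records),
        retrieved_at=datetime.now(timezone.utc),
        backend_id=backend.backend_id,
    )
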