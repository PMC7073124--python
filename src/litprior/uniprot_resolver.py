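"""Resolution of UniProt accessions / gene symbols to gene-name synonym sets.

Only reviewed (Swiss-Prot) entries supply synonyms; isoform accessions
(hyphen-digit suffix) and unreviewed (TrEMBL) entries resolve to an empty set
with a status explaining the Category-0 outcome downstream.
"""

from __future__ import annotations

import enum
import json
import logging
import re
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

logger = logging.getLogger(__name__)

_ISOFORM_RE = re.compile(r".+-\d+$")
# Swiss-Prot/TrEMBL accession syntax (6 or 10 characters), without isoform suffix.
_ACCESSION_RE = re.compile(
    r"^[OPQ][0-9][A-Z0-9]{3}[0-9]$|^[A-NR-Z][0-9]([A-Z][A-Z0-9]{2}[0-9]){1,2}$"
)


class IdType(enum.Enum):
    UNIPROT = "UNIPROT"
    GENE = "GENE"


class Scope(enum.Enum):
    """Where synonym and keyword must co-occur: title only, or title/abstract."""

    TITLE = "TITLE"
    TITLE_ABSTRACT = "TITLE_ABSTRACT"


class SynonymStatus(enum.Enum):
    OK = "OK"
    NO_SYNONYMS_ISOFORM = "NO_SYNONYMS_ISOFORM"
    NO_SYNONYMS_UNREVIEWED = "NO_SYNONYMS_UNREVIEWED"
    NO_SYNONYMS_NOT_FOUND = "NO_SYNONYMS_NOT_FOUND"


class RetrievalError(RuntimeError):
    """Transient transport failure; retryable, distinct from a missing entry."""


class UniProtParseError(ValueError):
    """Malformed backend record; the message names the offending field."""


@dataclass(frozen=True)
class QueryRow:
    """One user query: identifier, taxonomy, keywords, scope, date range."""

    identifier: str
    id_type: IdType
    taxonomy_id: int
    keywords: tuple[str, ...]
    scope: Scope = Scope.TITLE
    date_range: Optional[tuple[date, date]] = None
    row_label: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "identifier", self.identifier.strip())
        if not self.identifier:
            raise ValueError("identifier must be non-empty after trimming")
        if self.taxonomy_id <= 0:
            raise ValueError("taxonomy_id must be a positive NCBI taxid")
        kws = tuple(k.strip() for k in self.keywords)
        if not kws or any(not k for k in kws):
            raise ValueError("keywords must be a non-empty list of non-empty phrases")
        object.__setattr__(self, "keywords", kws)
        if self.date_range is not None and self.date_range[0] > self.date_range[1]:
            raise ValueError("date_range start must not exceed end")


@dataclass(frozen=True)
class UniProtEntry:
    accession: str
    reviewed: bool
    taxonomy_id: int
    gene_primary: Optional[str] = None
    gene_synonyms: tuple[str, ...] = ()
    protein_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen: set[str] = set()
        uniq = []
        for s in self.gene_synonyms:
            if s.lower() not in seen:
                seen.add(s.lower())
                uniq.append(s)
        object.__setattr__(self, "gene_synonyms", tuple(uniq))


@dataclass(frozen=True)
class SynonymSet:
    """Resolved search terms for one query; primary gene name first."""

    query: QueryRow
    names: tuple[str, ...]
    status: SynonymStatus
    source_accession: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.status is SynonymStatus.OK) != bool(self.names):
            raise ValueError("status OK iff names non-empty")
        lowered = [n.lower() for n in self.names]
        if len(set(lowered)) != len(lowered):
            raise ValueError("names must be unique case-insensitively")


def detect_isoform(accession: str) -> bool:
    """True iff the accession carries a UniProt isoform suffix (``-<digits>``)."""
    return bool(_ISOFORM_RE.match(accession))


def strip_isoform_suffix(accession: str) -> str:
    """Base accession with any isoform suffix removed."""
    return accession.rsplit("-", 1)[0] if detect_isoform(accession) else accession


def parse_uniprot_payload(raw) -> UniProtEntry:
    """Normalize one backend record (fixture JSON line/dict or REST JSON) to a
    :class:`UniProtEntry`.

    Fixture schema mirrors the entry fields one-to-one; UniProt REST responses
    (``primaryAccession`` / ``genes`` / ``organism`` keys) are mapped.
    """
    if isinstance(raw, (str, bytes)):
        try:
            raw = json.loads(raw)
        except json.JSONDecodeError as exc:
            raise UniProtParseError(f"record is not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise UniProtParseError("record must be a JSON object")

    if "primaryAccession" in raw:  # live REST shape
        accession = raw["primaryAccession"]
        reviewed = raw.get("entryType", "").lower().startswith("uniprotkb reviewed")
        try:
            taxid = int(raw["organism"]["taxonId"])
        except (KeyError, TypeError, ValueError) as exc:
            raise UniProtParseError("missing or malformed field 'organism.taxonId'") from exc
        genes = raw.get("genes") or []
        gene_primary = None
        synonyms: list[str] = []
        if genes:
            gene_primary = (genes[0].get("geneName") or {}).get("value")
            for g in genes:
                for s in g.get("synonyms") or []:
                    if s.get("value"):
                        synonyms.append(s["value"])
        protein_names: list[str] = []
        desc = raw.get("proteinDescription") or {}
        rec = (desc.get("recommendedName") or {}).get("fullName") or {}
        if rec.get("value"):
            protein_names.append(rec["value"])
        for alt in desc.get("alternativeNames") or []:
            v = (alt.get("fullName") or {}).get("value")
            if v:
                protein_names.append(v)
    else:  # fixture schema
        for fld in ("accession", "reviewed", "taxonomy_id"):
            if fld not in raw:
                raise UniProtParseError(f"missing field '{fld}'")
        accession = raw["accession"]
        reviewed = bool(raw["reviewed"])
        try:
            taxid = int(raw["taxonomy_id"])
        except (TypeError, ValueError) as exc:
            raise UniProtParseError("malformed field 'taxonomy_id'") from exc
        gene_primary = raw.get("gene_primary") or None
        synonyms = list(raw.get("gene_synonyms") or [])
        protein_names = list(raw.get("protein_names") or [])

    if not isinstance(accession, str) or not _ACCESSION_RE.match(
        strip_isoform_suffix(accession)
    ):
        raise UniProtParseError(f"malformed field 'accession': {accession!r}")
    return UniProtEntry(
        accession=accession,
        reviewed=reviewed,
        taxonomy_id=taxid,
        gene_primary=gene_primary,
        gene_synonyms=tuple(synonyms),
        protein_names=tuple(protein_names),
    )


class OfflineUniProtBackend:
    """Fixture directory backend: JSON-lines file, one UniProtEntry per line."""

    backend_id = "uniprot-fixture"

    def __init__(self, source: Path | str | Sequence[dict]):
        if isinstance(source, (str, Path)):
            path = Path(source)
            if path.is_dir():
                path = path / "uniprot.jsonl"
            lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
            self._entries = [parse_uniprot_payload(ln) for ln in lines]
        else:
            self._entries = [parse_uniprot_payload(rec) for rec in source]

    def get_by_accession(self, accession: str) -> Optional[UniProtEntry]:
        for e in self._entries:
            if e.accession == accession:
                return e
        return None

    def find_by_gene(self, symbol: str, taxonomy_id: int) -> list[UniProtEntry]:
        sym = symbol.lower()
        return [
            e
            for e in self._entries
            if e.reviewed
            and e.taxonomy_id == taxonomy_id
            and e.gene_primary is not None
            and e.gene_primary.lower() == sym
        ]


class LiveUniProtBackend:
    """UniProt REST lookup with on-disk caching keyed by accession+taxid.

    Caching makes reruns deterministic and keeps request volume polite; the
    cache file is plain JSON so a cached run needs no network at all.
    """

    backend_id = "uniprot-rest"
    BASE = "https://rest.uniprot.org/uniprotkb"

    def __init__(self, cache_dir: Optional[Path] = None, max_retries: int = 3):
        self.cache_dir = Path(cache_dir) if cache_dir else None
        self.max_retries = max_retries
        if self.cache_dir:
            self.cache_dir.mkdir(parents=True, exist_ok=True)

    def _cached_get(self, key: str, url: str) -> Optional[dict]:
        cache_file = self.cache_dir / f"{key}.json" if self.cache_dir else None
        if cache_file and cache_file.exists():
            return json.loads(cache_file.read_text())
        delay = 1.0
        for attempt in range(self.max_retries):
            try:
                with urllib.request.urlopen(url, timeout=30) as resp:
                    payload = json.loads(resp.read().decode("utf-8"))
                break
            except urllib.error.HTTPError as exc:
                if exc.code == 404:
                    payload = None
                    break
                if attempt == self.max_retries - 1:
                    raise RetrievalError(f"UniProt request failed: {exc}") from exc
                time.sleep(delay)
                delay *= 2
            except (urllib.error.URLError, TimeoutError) as exc:
                if attempt == self.max_retries - 1:
                    raise RetrievalError(f"UniProt unreachable: {exc}") from exc
                time.sleep(delay)
                delay *= 2
        if cache_file is not None:
            cache_file.write_text(json.dumps(payload))
        return payload

    def get_by_accession(self, accession: str) -> Optional[UniProtEntry]:
        payload = self._cached_get(f"acc_{accession}", f"{self.BASE}/{accession}.json")
        if payload is None:
            return None
        return parse_uniprot_payload(payload)

    def find_by_gene(self, symbol: str, taxonomy_id: int) -> list[UniProtEntry]:
        query = urllib.parse.quote(
            f"gene_exact:{symbol} AND organism_id:{taxonomy_id} AND reviewed:true"
        )
        payload = self._cached_get(
            f"gene_{symbol}_{taxonomy_id}",
            f"{self.BASE}/search?query={query}&format=json&size=25",
        )
        if not payload or not payload.get("results"):
            return []
        return [parse_uniprot_payload(r) for r in payload["results"]]


def _dedupe_ci(names: Sequence[str]) -> tuple[str, ...]:
    seen: set[str] = set()
    out = []
    for n in names:
        n = n.strip()
        if n and n.lower() not in seen:
            seen.add(n.lower())
            out.append(n)
    return tuple(out)


def _names_from_entry(entry: UniProtEntry, include_protein_names: bool) -> tuple[str, ...]:
    names: list[str] = []
    if entry.gene_primary:
        names.append(entry.gene_primary)
    names.extend(entry.gene_synonyms)
    if include_protein_names:
        names.extend(entry.protein_names)
    return _dedupe_ci(names)


def resolve_synonyms(
    row: QueryRow, backend, include_protein_names: bool = False
) -> SynonymSet:
    """Resolve a query row to its gene-name synonym set.

    Isoform accessions short-circuit without contacting the backend; unreviewed
    or missing entries, and entries whose taxonomy does not match the row,
    yield the corresponding empty-name status.
    """
    if row.id_type is IdType.UNIPROT:
        if detect_isoform(row.identifier):
            return SynonymSet(
                row, (), SynonymStatus.NO_SYNONYMS_ISOFORM, source_accession=row.identifier
            )
        entry = backend.get_by_accession(row.identifier)
        if entry is None or entry.taxonomy_id != row.taxonomy_id:
            return SynonymSet(row, (), SynonymStatus.NO_SYNONYMS_NOT_FOUND)
        if not entry.reviewed:
            return SynonymSet(
                row, (), SynonymStatus.NO_SYNONYMS_UNREVIEWED, source_accession=entry.accession
            )
    else:
        candidates = backend.find_by_gene(row.identifier, row.taxonomy_id)
        if not candidates:
            return SynonymSet(row, (), SynonymStatus.NO_SYNONYMS_NOT_FOUND)
        candidates = sorted(candidates, key=lambda e: e.accession)
        if len(candidates) > 1:
            logger.warning(
                "gene symbol %s (taxid %d) matches %d reviewed entries; using %s",
                row.identifier,
                row.taxonomy_id,
                len(candidates),
                candidates[0].accession,
            )
        entry = candidates[0]

    names = _names_from_entry(entry, include_protein_names)
    if not names:
        return SynonymSet(
            row, (), SynonymStatus.NO_SYNONYMS_NOT_FOUND, source_accession=entry.accession
        )
    return SynonymSet(row, names, SynonymStatus.OK, source_accession=entry.accession)
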