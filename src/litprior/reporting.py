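"""Assembly of the multi-tab spreadsheet report.

First tab: a summary row per input query (id, gene, synonyms, keyword, scope,
Total / Category / False, comment) followed by a category-distribution footer.
One further tab per query with the retrieved records (validation flag and
cluster label included) and the frequency tables. Every tab is mirrored as a
TSV file next to the workbook so downstream tooling never needs a
spreadsheet reader.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from openpyxl import Workbook, load_workbook

from .categorizer import CategoryResult, MatchResult
from .mesh_analytics import ClusterAssignment, FrequencyTable
from .pubmed_retrieval import ResultSet
from .uniprot_resolver import QueryRow, SynonymSet, SynonymStatus

SUMMARY_HEADER = (
    "UniProtID",
    "GeneName",
    "Synonyms",
    "Keywords",
    "Scope",
    "Total",
    "Category",
    "False",
    "Comment",
)
RECORD_HEADER = (
    "PMID",
    "Title",
    "Year",
    "Authors",
    "Journal",
    "PublicationTypes",
    "Matched",
    "Cluster",
)
_STATUS_COMMENT = {
    SynonymStatus.NO_SYNONYMS_ISOFORM: "no reviewed synonyms (isoform accession)",
    SynonymStatus.NO_SYNONYMS_UNREVIEWED: "no reviewed synonyms (unreviewed entry)",
    SynonymStatus.NO_SYNONYMS_NOT_FOUND: "no reviewed synonyms (entry not found)",
}
_TAB_FORBIDDEN = re.compile(r"[\\/?*\[\]:']")


@dataclass(frozen=True)
class ReportRow:
    uniprot_id: str
    gene_name: str
    synonyms_used: str
    keywords: str
    scope: str
    total: int
    category: int
    false_count: int
    comment: str = ""


@dataclass
class QueryOutcome:
    """Everything the report needs for one input query."""

    query: QueryRow
    synset: Optional[SynonymSet] = None
    result: Optional[CategoryResult] = None
    resultset: Optional[ResultSet] = None
    matches: tuple[MatchResult, ...] = ()
    clusters: Optional[ClusterAssignment] = None
    word_freq: Optional[FrequencyTable] = None
    mesh_freq: Optional[FrequencyTable] = None
    year_freq: Optional[FrequencyTable] = None
    error: Optional[str] = None


def _comment_for(o: QueryOutcome) -> str:
    if o.error:
        return f"row error: {o.error}"
    if o.synset is not None and o.synset.status is not SynonymStatus.OK:
        return _STATUS_COMMENT[o.synset.status]
    if o.result is not None and o.result.total > 0 and not o.result.matching_pmids:
        return "all retrieved records failed validation"
    return ""


def summary_table(outcomes: Sequence[QueryOutcome]) -> list[ReportRow]:
    """One ReportRow per input query, input order preserved."""
    rows = []
    for o in outcomes:
        q = o.query
        syn_names = o.synset.names if o.synset is not None else ()
        gene = syn_names[0] if syn_names else ""
        res = o.result
        rows.append(
            ReportRow(
                uniprot_id=q.identifier,
                gene_name=gene,
                synonyms_used=";".join(syn_names),
                keywords=";".join(q.keywords),
                scope=q.scope.value,
                total=res.total if res else 0,
                category=res.category if res else 0,
                false_count=res.false_count if res else 0,
                comment=_comment_for(o),
            )
        )
    return rows


def category_distribution(rows: Sequence[ReportRow]) -> list[tuple[str, int]]:
    return [
        (f"Category {c}", sum(1 for r in rows if r.category == c)) for c in (0, 1, 2, 3)
    ]


def _tab_name(base: str, used: set[str]) -> str:
    name = _TAB_FORBIDDEN.sub("_", base) or "query"
    name = name[:31]
    if name in used:
        i = 2
        while True:
            suffix = f"_{i}"
            cand = name[: 31 - len(suffix)] + suffix
            if cand not in used:
                name = cand
                break
            i += 1
    used.add(name)
    return name


def _summary_grid(rows: Sequence[ReportRow]) -> list[list]:
    grid: list[list] = [list(SUMMARY_HEADER)]
    for r in rows:
        grid.append(
            [
                r.uniprot_id,
                r.gene_name,
                r.synonyms_used,
                r.keywords,
                r.scope,
                r.total,
                r.category,
                r.false_count,
                r.comment,
            ]
        )
    grid.append([])
    grid.append(["Category distribution"])
    for label, count in category_distribution(rows):
        grid.append([label, count])
    return grid


def _freq_section(title: str, table: Optional[FrequencyTable]) -> list[list]:
    grid: list[list] = [[], [title], ["Term", "Count"]]
    if table is not None:
        for term, count in table.items():
            grid.append([term, count])
    return grid


def _query_grid(o: QueryOutcome) -> list[list]:
    grid: list[list] = [list(RECORD_HEADER)]
    matched = {m.pmid: m.matched for m in o.matches}
    labels = o.clusters.labels if o.clusters is not None else {}
    records = o.resultset.records if o.resultset is not None else ()
    for r in records:
        grid.append(
            [
                r.pmid,
                r.title,
                r.year if r.year is not None else "",
                "; ".join(r.authors),
                r.journal or "",
                "; ".join(r.publication_types),
                bool(matched.get(r.pmid, False)),
                labels.get(r.pmid, ""),
            ]
        )
    grid.extend(_freq_section("Abstract word frequencies", o.word_freq))
    grid.extend(_freq_section("MeSH term frequencies", o.mesh_freq))
    grid.extend(_freq_section("Publications per year", o.year_freq))
    return grid


def _write_tsv(grid: Sequence[Sequence], path: Path) -> None:
    lines = []
    for row in grid:
        lines.append("\t".join("" if c is None else str(c) for c in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_report(
    rows: Sequence[ReportRow],
    outcomes: Sequence[QueryOutcome],
    path: Path | str,
) -> Path:
    """Write the XLSX workbook (summary first, one tab per query) and TSV
    mirrors of every tab (``<stem>.<tab>.tsv`` next to the workbook)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    wb = Workbook()
    ws = wb.active
    ws.title = "Summary"
    used = {"Summary"}
    summary = _summary_grid(rows)
    for row in summary:
        ws.append(row)
    _write_tsv(summary, path.with_name(f"{path.stem}.Summary.tsv"))
    for o in outcomes:
        base = ""
        if o.synset is not None and o.synset.names:
            base = o.synset.names[0]
        tab = _tab_name(base or o.query.identifier, used)
        ws_q = wb.create_sheet(title=tab)
        grid = _query_grid(o)
        for row in grid:
            ws_q.append(row)
        _write_tsv(grid, path.with_name(f"{path.stem}.{tab}.tsv"))
    wb.save(path)
    return path


def read_summary(path: Path | str) -> list[ReportRow]:
    """Read the summary tab back into ReportRows (rows up to the footer)."""
    wb = load_workbook(Path(path), read_only=True)
    ws = wb["Summary"]
    rows: list[ReportRow] = []
    it = ws.iter_rows(values_only=True)
    header = next(it)
    if tuple(header[: len(SUMMARY_HEADER)]) != SUMMARY_HEADER:
        raise ValueError("summary tab header does not match the report schema")
    for values in it:
        if values is None or all(v is None for v in values):
            break
        v = list(values) + [None] * (len(SUMMARY_HEADER) - len(values))
        rows.append(
            ReportRow(
                uniprot_id=str(v[0] or ""),
                gene_name=str(v[1] or ""),
                synonyms_used=str(v[2] or ""),
                keywords=str(v[3] or ""),
                scope=str(v[4] or ""),
                total=int(v[5]),
                category=int(v[6]),
                false_count=int(v[7]),
                comment=str(v[8] or ""),
            )
        )
    wb.close()
    return rows
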