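"""End-to-end orchestration and the command-line interface.

Per input row: resolve synonyms → (if resolvable) build the expanded query →
fetch records → validate and categorize → MeSH clustering and frequency
summaries → report. Rows are isolated: a failure in one row lands in that
row's comment column and never aborts the batch.

Exit codes: 0 clean, 1 at least one row errored, 2 fatal (unreadable input,
invalid configuration).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

import click
import pandas as pd

from . import fixture_corpus, mesh_analytics, reporting
from .categorizer import categorize, record_matches
from .mesh_analytics import DEFAULT_CLUSTERS
from .pubmed_retrieval import (
    LivePubMedBackend,
    OfflinePubMedBackend,
    fetch_records,
)
from .query_builder import build_query
from .reporting import QueryOutcome
from .uniprot_resolver import (
    IdType,
    LiveUniProtBackend,
    OfflineUniProtBackend,
    QueryRow,
    Scope,
    SynonymStatus,
    resolve_synonyms,
)

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("Identifier", "IdType", "TaxonomyID", "Keywords", "TitleOnly")


class BackendKind(enum.Enum):
    LIVE = "LIVE"
    FIXTURE = "FIXTURE"


class InputError(ValueError):
    """Fatal input problem (missing file or mandatory column)."""


@dataclass
class RunConfig:
    input_path: Path
    output_path: Path
    backend: BackendKind = BackendKind.FIXTURE
    fixture_dir: Optional[Path] = None
    scope_default: Scope = Scope.TITLE
    clusters: int = DEFAULT_CLUSTERS
    contact_email: Optional[str] = None
    api_key: Optional[str] = None
    date_range: Optional[tuple[date, date]] = None
    all_keywords: bool = False
    include_protein_names: bool = False
    cache_dir: Optional[Path] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.clusters < 1:
            raise ValueError("clusters must be >= 1")
        if self.backend is BackendKind.LIVE and not self.contact_email:
            raise ValueError("LIVE backend requires a contact email")
        if self.backend is BackendKind.FIXTURE and self.fixture_dir is None:
            raise ValueError("FIXTURE backend requires fixture_dir")


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1", "yes", "y"):
        return True
    if s in ("false", "0", "no", "n"):
        return False
    raise ValueError(f"not a boolean: {value!r}")


def parse_input_sheet(
    path: Path | str, scope_default: Scope = Scope.TITLE
) -> tuple[list[QueryRow], list[tuple[int, str]]]:
    """Read the query table (CSV/TSV/XLSX by extension).

    Returns validated rows in file order plus a rejects list of
    (row_label, reason) for malformed rows. A missing mandatory column is
    fatal.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    if path.suffix == ".xlsx":
        df = pd.read_excel(path, dtype=str)
    elif path.suffix == ".tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"missing mandatory column(s): {', '.join(missing)}")

    rows: list[QueryRow] = []
    rejects: list[tuple[int, str]] = []
    for i, rec in enumerate(df.to_dict(orient="records")):
        try:
            id_type = IdType[str(rec["IdType"]).strip().upper()]
            taxid = int(str(rec["TaxonomyID"]).strip())
            keywords = tuple(
                k.strip() for k in str(rec["Keywords"]).split(";") if k.strip()
            )
            scope = (
                Scope.TITLE if _parse_bool(rec["TitleOnly"]) else Scope.TITLE_ABSTRACT
            )
            date_range = None
            start, end = rec.get("DateStart"), rec.get("DateEnd")
            if isinstance(start, str) and start.strip() and isinstance(end, str) and end.strip():
                date_range = (date.fromisoformat(start.strip()), date.fromisoformat(end.strip()))
            rows.append(
                QueryRow(
                    identifier=str(rec["Identifier"]),
                    id_type=id_type,
                    taxonomy_id=taxid,
                    keywords=keywords,
                    scope=scope,
                    date_range=date_range,
                    row_label=i,
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            rejects.append((i, str(exc)))
    return rows, rejects


def process_query(
    row: QueryRow,
    uniprot_backend,
    pubmed_backend,
    clusters: int = DEFAULT_CLUSTERS,
    all_keywords: bool = False,
    include_protein_names: bool = False,
) -> QueryOutcome:
    """Run the full per-row pipeline, capturing any failure in the outcome."""
    outcome = QueryOutcome(query=row)
    try:
        syns = resolve_synonyms(
            row, uniprot_backend, include_protein_names=include_protein_names
        )
        outcome.synset = syns
        if syns.status is not SynonymStatus.OK:
            outcome.result = categorize(syns, None, row.keywords, row.scope)
            return outcome
        q = build_query(
            syns, row.keywords, row.scope, date_range=row.date_range, all_keywords=all_keywords
        )
        logger.info(
            "row %d: query=%s backend=%s", row.row_label, q.text, pubmed_backend.backend_id
        )
        rs = fetch_records(q, pubmed_backend)
        outcome.resultset = rs
        outcome.matches = tuple(
            record_matches(r, syns, row.keywords, row.scope, all_keywords=all_keywords)
            for r in rs.records
        )
        outcome.result = categorize(
            syns, rs, row.keywords, row.scope, all_keywords=all_keywords
        )
        logger.info(
            "row %d: total=%d category=%d false=%d",
            row.row_label,
            outcome.result.total,
            outcome.result.category,
            outcome.result.false_count,
        )
        if rs.records:
            matrix = mesh_analytics.mesh_matrix(rs.records)
            if not matrix.empty:
                outcome.clusters = mesh_analytics.hcluster(matrix, k=clusters)
            outcome.word_freq = mesh_analytics.word_frequencies(rs.records)
            outcome.mesh_freq = mesh_analytics.mesh_frequencies(rs.records)
            outcome.year_freq = mesh_analytics.year_histogram(rs.records)
    except Exception as exc:  # row isolation: one bad row must not kill a batch
        logger.exception("row %d failed", row.row_label)
        outcome.error = str(exc)
    return outcome


def make_backends(config: RunConfig):
    if config.backend is BackendKind.FIXTURE:
        return (
            OfflineUniProtBackend(config.fixture_dir),
            OfflinePubMedBackend(config.fixture_dir),
        )
    return (
        LiveUniProtBackend(cache_dir=config.cache_dir),
        LivePubMedBackend(
            email=config.contact_email, api_key=config.api_key, cache_dir=config.cache_dir
        ),
    )


def run(config: RunConfig) -> int:
    """Execute a full batch run and write the report. Returns the exit code."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    rows, rejects = parse_input_sheet(config.input_path, config.scope_default)
    uniprot_backend, pubmed_backend = make_backends(config)
    outcomes = [
        process_query(
            row,
            uniprot_backend,
            pubmed_backend,
            clusters=config.clusters,
            all_keywords=config.all_keywords,
            include_protein_names=config.include_protein_names,
        )
        for row in rows
    ]
    summary = reporting.summary_table(outcomes)
    reporting.write_report(summary, outcomes, config.output_path)
    for label, reason in rejects:
        logger.error("input row %d rejected: %s", label, reason)
    errored = any(o.error for o in outcomes) or bool(rejects)
    return 1 if errored else 0


@click.group()
def main() -> None:
    """Literature-based prioritization of omics candidate lists."""


@main.command("run")
@click.option("--input", "input_path", required=True, type=click.Path(path_type=Path))
@click.option("--output", "output_path", required=True, type=click.Path(path_type=Path))
@click.option(
    "--backend",
    type=click.Choice(["live", "fixture"], case_sensitive=False),
    default="fixture",
    show_default=True,
)
@click.option("--fixture-dir", type=click.Path(path_type=Path), default=None)
@click.option("--email", "contact_email", default=None, help="Contact email (live mode).")
@click.option("--api-key", default=None)
@click.option("--clusters", type=int, default=DEFAULT_CLUSTERS, show_default=True)
@click.option("--all-keywords", is_flag=True, help="AND-combine keywords instead of OR.")
@click.option(
    "--include-protein-names",
    is_flag=True,
    help="Add UniProt protein names to the synonym universe.",
)
@click.option("--cache-dir", type=click.Path(path_type=Path), default=None)
@click.option("--log-level", default="INFO", show_default=True)
def run_cmd(
    input_path, output_path, backend, fixture_dir, contact_email, api_key,
    clusters, all_keywords, include_protein_names, cache_dir, log_level,
) -> None:
    """Run the pipeline over an input query table."""
    try:
        config = RunConfig(
            input_path=input_path,
            output_path=output_path,
            backend=BackendKind[backend.upper()],
            fixture_dir=fixture_dir,
            clusters=clusters,
            contact_email=contact_email,
            api_key=api_key,
            all_keywords=all_keywords,
            include_protein_names=include_protein_names,
            cache_dir=cache_dir,
            log_level=log_level,
        )
        code = run(config)
    except (InputError, ValueError) as exc:
        click.echo(f"fatal: {exc}", err=True)
        raise SystemExit(2)
    raise SystemExit(code)


@main.command("make-fixtures")
@click.option("--out", "outdir", required=True, type=click.Path(path_type=Path))
@click.option("--seed", type=int, default=0, show_default=True)
def make_fixtures_cmd(outdir: Path, seed: int) -> None:
    """Generate the demonstration fixture corpus and matching input sheet."""
    spec = fixture_corpus.demo_spec(seed=seed)
    fixture_corpus.generate_corpus(spec, outdir)
    fixture_corpus.generate_input_sheet(spec, Path(outdir) / "queries.csv")
    click.echo(f"fixture corpus written to {outdir}")


if __name__ == "__main__":
    main()
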