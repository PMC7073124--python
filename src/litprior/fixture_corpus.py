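"""Deterministic generation of offline UniProt + PubMed fixture corpora.

Each corpus is planned per query: how many matching review articles, how many
matching original articles, and how many non-matching ("False") distractor
records to emit. Matching records embed a randomly chosen synonym together
with the keyword as standalone whole words, either in the title or only in
the abstract; distractor records carry the keyword but no synonym in their
visible metadata, with the synonym hidden in the ``index_extra`` field so the
offline searcher still returns them — emulating PubMed hits whose fetched
metadata lacks the query terms. MeSH descriptors are drawn from per-cluster
signatures (3 core descriptors each plus random noise) so cluster recovery
is testable. A fixed seed yields a byte-identical corpus.
"""

from __future__ import annotations

import enum
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .uniprot_resolver import Scope

SCHEMA_VERSION = 1


class Placement(enum.Enum):
    TITLE = "TITLE"
    ABSTRACT_ONLY = "ABSTRACT_ONLY"


class CorpusSpecError(ValueError):
    """Inconsistent corpus plan."""


@dataclass(frozen=True)
class QueryPlan:
    """Plan for one query and its retrievable record set."""

    accession: str
    gene: str
    synonyms: tuple[str, ...] = ()
    taxonomy_id: int = 9606
    keyword: str = "cancer"
    n_matching_reviews: int = 0
    n_matching_articles: int = 0
    n_nonmatching: int = 0
    placement: Placement = Placement.TITLE
    scope: Scope = Scope.TITLE
    reviewed: bool = True

    def validate(self) -> None:
        if min(self.n_matching_reviews, self.n_matching_articles, self.n_nonmatching) < 0:
            raise CorpusSpecError("record counts must be >= 0")
        if (
            self.placement is Placement.ABSTRACT_ONLY
            and self.scope is Scope.TITLE
            and (self.n_matching_reviews or self.n_matching_articles)
        ):
            raise CorpusSpecError(
                f"{self.gene}: ABSTRACT_ONLY placement can never match under TITLE scope"
            )


@dataclass(frozen=True)
class CorpusSpec:
    seed: int
    plans: tuple[QueryPlan, ...]
    mesh_pool: tuple[str, ...] = (
        "Thyroid Neoplasms",
        "Neoplasm Metastasis",
        "Biomarkers, Tumor",
        "Proteomics",
        "Gene Expression Regulation, Neoplastic",
        "Colorectal Neoplasms",
        "Mass Spectrometry",
        "Cell Movement",
        "Prognosis",
        "Neuroblastoma",
        "Cell Line, Tumor",
        "Signal Transduction",
    )
    year_range: tuple[int, int] = (2000, 2018)
    n_signatures: int = 4

    def validate(self) -> None:
        if not self.plans:
            return
        for p in self.plans:
            p.validate()
        if self.year_range[0] > self.year_range[1]:
            raise CorpusSpecError("year_range min must not exceed max")
        if len(self.mesh_pool) < 3 * self.n_signatures:
            raise CorpusSpecError("mesh_pool too small for the signature count")


_MATCH_TITLES = (
    "{syn} expression in {kw}: evidence from a clinical cohort",
    "Role of {syn} in {kw} progression",
    "{syn} is a candidate prognostic marker of {kw}",
    "Targeting {syn} signalling pathways in {kw}",
    "Elevated {syn} levels predict outcome in {kw}",
)
_REVIEW_TITLES = (
    "{syn} and {kw}: a systematic review",
    "The emerging roles of {syn} in {kw}: review of the literature",
)
_NEUTRAL_TITLES = (
    "A proteomic survey of archived tumour tissue specimens",
    "Quantitative profiling of clinical biopsy material",
    "Longitudinal molecular monitoring in a hospital cohort",
)
_DISTRACTOR_TITLES = (
    "Advances in {kw} screening programmes",
    "Population trends in {kw} incidence and survival",
    "Imaging modalities for early {kw} detection",
)
_ABSTRACT_SENTENCES = (
    "We analysed tissue specimens using quantitative mass spectrometry.",
    "Differential abundance was assessed across patient groups.",
    "Results were validated in an independent clinical cohort.",
    "Pathway analysis suggested involvement of cytoskeletal remodelling.",
)
_SURNAMES = ("Fischer", "Okafor", "Tanaka", "Silva", "Novak", "Dubois", "Larsen", "Hoffmann")
_JOURNALS = (
    "Journal of Molecular Oncology",
    "Clinical Proteomics Reports",
    "Tumour Biology Letters",
)
_COUNTRIES = ("Germany", "Australia", "Japan", "Brazil")


def _signature_groups(spec: CorpusSpec) -> list[tuple[str, ...]]:
    pool = spec.mesh_pool
    return [tuple(pool[3 * i : 3 * i + 3]) for i in range(spec.n_signatures)]


def _record_text(plan: QueryPlan, rng: random.Random, review: bool) -> tuple[str, str]:
    syn = rng.choice((plan.gene,) + plan.synonyms)
    templates = _REVIEW_TITLES if review else _MATCH_TITLES
    if plan.placement is Placement.TITLE:
        title = rng.choice(templates).format(syn=syn, kw=plan.keyword)
        abstract = " ".join(
            rng.sample(_ABSTRACT_SENTENCES, k=2)
            + [f"These findings link {syn} to {plan.keyword} biology."]
        )
    else:
        title = rng.choice(_NEUTRAL_TITLES)
        abstract = " ".join(
            rng.sample(_ABSTRACT_SENTENCES, k=2)
            + [f"We report that {syn} is associated with {plan.keyword} in this setting."]
        )
    return title, abstract


def plan_records(
    plan: QueryPlan,
    rng: random.Random,
    signatures: Sequence[tuple[str, ...]],
    noise_pool: Sequence[str],
    year_range: tuple[int, int],
    pmid_start: int,
) -> list[dict]:
    """Materialize one plan into raw fixture record dicts (pmids sequential
    from ``pmid_start``; counts never depend on the rng draw)."""
    plan.validate()
    records: list[dict] = []
    kinds = (
        ["review"] * plan.n_matching_reviews
        + ["article"] * plan.n_matching_articles
        + ["false"] * plan.n_nonmatching
    )
    for offset, kind in enumerate(kinds):
        pmid = str(pmid_start + offset)
        sig = signatures[rng.randrange(len(signatures))] if signatures else ()
        mesh = list(sig) + [d for d in noise_pool if d not in sig and rng.random() < 0.15]
        rec: dict = {
            "pmid": pmid,
            "year": rng.randint(*year_range),
            "authors": [
                f"{rng.choice(_SURNAMES)} {chr(rng.randint(65, 90))}" for _ in range(2)
            ],
            "country": rng.choice(_COUNTRIES),
            "mesh_terms": mesh,
            "journal": rng.choice(_JOURNALS),
        }
        if kind == "false":
            rec["title"] = rng.choice(_DISTRACTOR_TITLES).format(kw=plan.keyword)
            rec["abstract"] = " ".join(rng.sample(_ABSTRACT_SENTENCES, k=2))
            rec["publication_types"] = ["Journal Article"]
            # hidden indexed synonym: retrievable, but invisible to validation
            rec["index_extra"] = [plan.gene]
        else:
            review = kind == "review"
            title, abstract = _record_text(plan, rng, review)
            rec["title"] = title
            rec["abstract"] = abstract
            rec["publication_types"] = ["Review"] if review else ["Journal Article"]
        records.append(rec)
    return records


def generate_corpus(spec: CorpusSpec, outdir: Path | str) -> Path:
    """Write the fixture directory: uniprot.jsonl + pubmed.jsonl + manifest.

    Deterministic: the same spec (including seed) reproduces byte-identical
    files; changing only the seed reshuffles surface text but never the
    planned counts or categories.
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    signatures = _signature_groups(spec)
    noise_pool = spec.mesh_pool[3 * spec.n_signatures :] or spec.mesh_pool

    uniprot_lines = []
    for plan in spec.plans:
        uniprot_lines.append(
            json.dumps(
                {
                    "accession": plan.accession,
                    "reviewed": plan.reviewed,
                    "taxonomy_id": plan.taxonomy_id,
                    "gene_primary": plan.gene,
                    "gene_synonyms": list(plan.synonyms),
                    "protein_names": [f"{plan.gene} protein"],
                },
                sort_keys=True,
            )
        )

    pubmed_lines = []
    pmid_next = 100001
    for plan in spec.plans:
        recs = plan_records(
            plan, rng, signatures, noise_pool, spec.year_range, pmid_next
        )
        pmid_next += len(recs)
        pubmed_lines.extend(json.dumps(r, sort_keys=True) for r in recs)

    (outdir / "uniprot.jsonl").write_text("\n".join(uniprot_lines) + ("\n" if uniprot_lines else ""))
    (outdir / "pubmed.jsonl").write_text("\n".join(pubmed_lines) + ("\n" if pubmed_lines else ""))
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": spec.seed,
        "files": {"uniprot": "uniprot.jsonl", "pubmed": "pubmed.jsonl"},
        "n_queries": len(spec.plans),
        "n_records": len(pubmed_lines),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    return outdir


def generate_input_sheet(
    spec: CorpusSpec, path: Path | str, extra_rows: Sequence[dict] = ()
) -> Path:
    """Write the query table matching the CLI input schema (one row per plan;
    format chosen by extension: .csv, .tsv or .xlsx)."""
    path = Path(path)
    rows = [
        {
            "Identifier": plan.accession,
            "IdType": "UNIPROT",
            "TaxonomyID": plan.taxonomy_id,
            "Keywords": plan.keyword,
            "TitleOnly": plan.scope is Scope.TITLE,
        }
        for plan in spec.plans
    ] + list(extra_rows)
    df = pd.DataFrame(
        rows, columns=["Identifier", "IdType", "TaxonomyID", "Keywords", "TitleOnly"]
    )
    if path.suffix == ".xlsx":
        df.to_excel(path, index=False)
    elif path.suffix == ".tsv":
        df.to_csv(path, sep="\t", index=False)
    else:
        df.to_csv(path, index=False)
    return path


def demo_spec(seed: int = 0) -> CorpusSpec:
    """A small corpus exercising every category: one review-rich query, one
    with original articles only, one with no contextual hits, plus a
    distractor-only query."""
    return CorpusSpec(
        seed=seed,
        plans=(
            QueryPlan(
                accession="Q15582",
                gene="TGFBI",
                synonyms=("BIGH3",),
                keyword="cancer",
                n_matching_reviews=1,
                n_matching_articles=16,
                n_nonmatching=1,
            ),
            QueryPlan(
                accession="P07585",
                gene="DCN",
                synonyms=("SLRR1B", "PG40"),
                keyword="cancer",
                n_matching_reviews=0,
                n_matching_articles=2,
            ),
            QueryPlan(
                accession="O15511",
                gene="ARPC5",
                synonyms=("ARC16",),
                keyword="cancer",
            ),
        ),
    )
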