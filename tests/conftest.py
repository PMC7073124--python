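"""Shared fixtures and independent brute-force oracles.

The oracles re-derive the validation/categorization rules and the
agglomerative clustering from first principles, using token-list containment
and plain-math cosine rather than the package's regex/scipy code paths, so
the two routes stay independent.
"""

from __future__ import annotations

import math
import random
import re

import pytest

from litprior import (
    IdType,
    OfflinePubMedBackend,
    QueryRow,
    Scope,
    SynonymSet,
    SynonymStatus,
    demo_spec,
    generate_corpus,
    generate_input_sheet,
)
from litprior.uniprot_resolver import OfflineUniProtBackend


# ---------------------------------------------------------------------------
# oracle: whole-word phrase containment via token-list matching


def oracle_contains(phrase: str, text: str) -> bool:
    toks = re.findall(r"[A-Za-z0-9]+", text.lower())
    want = re.findall(r"[A-Za-z0-9]+", phrase.lower())
    if not want:
        return False
    for i in range(len(toks) - len(want) + 1):
        if toks[i : i + len(want)] == want:
            return True
    return False


def oracle_record_matched(record, synonyms, keywords, scope, all_keywords=False) -> bool:
    text = record.title if scope is Scope.TITLE else record.title + " " + record.abstract
    has_syn = any(oracle_contains(s, text) for s in synonyms)
    if all_keywords:
        has_kw = all(oracle_contains(k, text) for k in keywords)
    else:
        has_kw = any(oracle_contains(k, text) for k in keywords)
    return has_syn and has_kw


def oracle_categorize(records, synonyms, keywords, scope, all_keywords=False):
    """Independent re-derivation of the category rules: returns
    (total, category, false_count)."""
    matched = [
        r for r in records
        if oracle_record_matched(r, synonyms, keywords, scope, all_keywords)
    ]
    reviews = [
        r for r in matched
        if any("review" in t.lower() for t in r.publication_types)
    ]
    if reviews:
        cat = 1
    elif matched:
        cat = 2
    else:
        cat = 3
    return len(records), cat, len(records) - len(matched)


# ---------------------------------------------------------------------------
# oracle: brute-force agglomerative clustering on cosine distances


def oracle_cosine(a, b) -> float:
    dot = sum(x * y for x, y in zip(a, b))
    na = math.sqrt(sum(x * x for x in a))
    nb = math.sqrt(sum(y * y for y in b))
    return 1.0 - dot / (na * nb)


def _oracle_pmid_key(pmid: str):
    return (0, len(pmid), pmid) if pmid.isdigit() else (1, 0, pmid)


def oracle_hcluster(pmids, vectors, k, linkage="average"):
    """Brute-force agglomeration over frozensets, recomputing linkage
    distances from the base pairwise matrix at every step. Returns the
    partition as a set of frozensets of pmids."""
    base = {
        (pmids[i], pmids[j]): oracle_cosine(vectors[i], vectors[j])
        for i in range(len(pmids))
        for j in range(len(pmids))
        if i != j
    }
    agg = {"average": lambda v: sum(v) / len(v), "single": min, "complete": max}[linkage]
    clusters = [frozenset([p]) for p in pmids]
    while len(clusters) > min(k, len(pmids)):
        best = None
        for ci in clusters:
            for cj in clusters:
                if ci == cj:
                    continue
                ri = min(ci, key=_oracle_pmid_key)
                rj = min(cj, key=_oracle_pmid_key)
                if _oracle_pmid_key(ri) > _oracle_pmid_key(rj):
                    continue
                d = agg([base[(a, b)] for a in ci for b in cj])
                cand = (d, _oracle_pmid_key(ri), _oracle_pmid_key(rj))
                if best is None or cand < best[0]:
                    best = (cand, ci, cj)
        _, ci, cj = best
        clusters = [c for c in clusters if c not in (ci, cj)] + [ci | cj]
    return {frozenset(c) for c in clusters}


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def demo_corpus_dir(tmp_path_factory):
    """The demonstration fixture corpus plus matching input sheet."""
    d = tmp_path_factory.mktemp("corpus")
    spec = demo_spec(seed=7)
    generate_corpus(spec, d)
    generate_input_sheet(spec, d / "queries.csv")
    return d


@pytest.fixture(scope="session")
def demo_backends(demo_corpus_dir):
    return OfflineUniProtBackend(demo_corpus_dir), OfflinePubMedBackend(demo_corpus_dir)


@pytest.fixture
def ok_synset():
    """A resolved synonym set for a decorin-like query."""
    row = QueryRow("P07585", IdType.UNIPROT, 9606, ("cancer",), Scope.TITLE)
    return SynonymSet(
        row, ("DCN", "SLRR1B", "PG40"), SynonymStatus.OK, source_accession="P07585"
    )


def make_record(pmid="1", title="", abstract="", year=2015, mesh=(), types=("Journal Article",)):
    from litprior import PubMedRecord

    return PubMedRecord(
        pmid=pmid,
        title=title,
        abstract=abstract,
        year=year,
        mesh_terms=tuple(mesh),
        publication_types=tuple(types),
    )


@pytest.fixture
def record_factory():
    return make_record


def random_plan(rng: random.Random, gene: str, accession: str, scope=None):
    """A randomized per-query record plan for property tests."""
    from litprior import Placement, QueryPlan

    scope = scope or rng.choice([Scope.TITLE, Scope.TITLE_ABSTRACT])
    placement = (
        Placement.TITLE
        if scope is Scope.TITLE
        else rng.choice([Placement.TITLE, Placement.ABSTRACT_ONLY])
    )
    return QueryPlan(
        accession=accession,
        gene=gene,
        synonyms=(gene + "L1", gene + "B"),
        keyword=rng.choice(["cancer", "metastasis"]),
        n_matching_reviews=rng.randint(0, 3),
        n_matching_articles=rng.randint(0, 6),
        n_nonmatching=rng.randint(0, 3),
        placement=placement,
        scope=scope,
    )
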