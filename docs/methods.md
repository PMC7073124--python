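# Methods

## The procedure

Each input row (UniProt accession or gene symbol, NCBI taxonomy id, keyword
list, scope flag, optional date range) is processed independently:

1. **Synonym resolution.** Accessions with an isoform suffix (`-<digits>`)
   are rejected immediately — splice isoforms are not independent literature
   subjects and UniProt synonym records attach to the canonical entry. For
   canonical accessions the entry must be reviewed (Swiss-Prot) and its
   taxonomy must match the row; the synonym universe is the primary gene
   name plus all recorded gene synonyms, deduplicated case-insensitively in
   record order. Gene-symbol input is resolved through the same backend
   (reviewed entries, exact primary-symbol match, given taxonomy); if several
   entries match, the lexicographically smallest accession is used and a
   warning logged. Any failure yields an empty synonym set with a status
   that maps to Category 0 downstream — retrieval is skipped entirely for
   such rows, so their Total is 0.
2. **Query building.** The expanded query is
   `(syn1 OR syn2 OR ...) AND (kw1 OR kw2 OR ...) [AND date-interval]`, each
   term an exact-phrase token tagged `[TI]` (strict, title-only) or `[TIAB]`
   (lenient, title-or-abstract). Multiple keywords are OR-combined by
   default to maximize recall; an `all_keywords` option switches to AND.
   Phrases are double-quoted and PubMed-reserved characters are stripped with
   a warning. The taxonomy identifier is deliberately *not* embedded in the
   PubMed query: species terms rarely appear in titles and the taxonomy
   constraint is already enforced during synonym resolution.
3. **Retrieval.** Live mode uses E-utilities esearch/efetch (≤3 requests/s
   without an API key, exponential backoff, optional disk cache keyed by the
   query hash). Offline mode searches a JSON-lines fixture corpus with the
   same whole-word co-occurrence semantics the validator uses. Both modes
   deduplicate by PMID and order records by descending year, then PMID; a
   date range is applied server-side (PDAT) in live mode and re-applied
   client-side in both modes, dropping undated records (with a warning)
   only when a range is set.
4. **Validation and categorization.** A record is validated when some
   synonym and some keyword each occur as case-insensitive whole words or
   phrases within the scoped fields. Records failing the check are counted
   as "False": they remain in the Total but contribute no evidence. A query
   is Category 1 with ≥1 validated review (any publication type containing
   the token "review"), Category 2 with validated publications but no
   review, Category 3 with none. When every retrieved record fails
   validation the rule is applied literally (Category 3) and the summary row
   carries the comment "all retrieved records failed validation".
5. **MeSH analytics.** Records are embedded as binary MeSH-descriptor
   incidence vectors (subheading qualifiers stripped; descriptors occur at
   most once per record, so binary weighting loses nothing). Pairwise cosine
   distances feed an agglomerative clustering cut at min(k, n) clusters,
   k = 4 by default. Abstract word frequencies (the word-cloud data), MeSH
   frequencies and the publication-year histogram are tabulated; graphics
   are out of scope — the tables are the output.
6. **Reporting.** Summary tab (one row per query, input order, category
   distribution footer) plus one tab per query; every tab is mirrored as
   TSV. Tab names use the primary gene name, fall back to the accession, are
   truncated to 31 characters and deduplicated with `_2`, `_3`, ... Reports
   are a pure function of the pipeline outputs; reruns in fixture mode are
   byte-identical (the TSVs literally so; XLSX content equal on read-back).

## Parameters that matter

| Parameter | Default | Notes |
|---|---|---|
| scope | TITLE | strict search; TITLE_ABSTRACT requires both terms anywhere in title/abstract |
| keyword combination | OR | `all_keywords` switches to AND |
| clusters k | 4 | cut height of the MeSH dendrogram; capped at the document count |
| linkage | average | single/complete available; average is the usual choice for sparse binary incidence data |
| synonym universe | gene names only | `include_protein_names` adds UniProt protein names (often too long to appear verbatim in titles) |
| tokenizer | letters only, ≥3 chars, fixed stopword list | digits stripped, so "p53" → "p" → dropped; `keep_alphanumeric` retains such tokens |

## Numerical and tie-breaking choices

- Cosine distance is clipped to [0, 1]; zero vectors are excluded upstream
  (documents without MeSH terms are reported as unclustered, and a corpus
  with no MeSH at all yields "no clustering" rather than an error).
- Agglomerative merges break distance ties by the smallest pair of
  cluster-representative PMIDs, and documents are canonically ordered by
  PMID before clustering, so cluster labels are deterministic and invariant
  under input-order permutation. Labels 1..k are assigned by ascending
  representative PMID.
- Whole-word matching uses alphanumeric-boundary guards, so synonym "CAT"
  does not match "catalytic", while hyphenated contexts ("CAT-positive")
  still match.
- One row's failure (bad identifier, malformed record) is captured in that
  row's comment column; the batch continues and the exit status signals the
  partial failure.

## The fixture generator

The generator emulates the structure of PubMed result sets, not their
surface realism: per query it plans exact counts of matching reviews,
matching original articles and non-matching distractors; titles/abstracts
are template sentences with the synonym and keyword slot-filled as
standalone words (so whole-word matching is guaranteed); reviews carry
publication type "Review"; MeSH descriptors are drawn from per-cluster
signatures (3 core descriptors plus noise at probability 0.15); years are
uniform over a configurable range. Distractor records contain the keyword
but no synonym in their visible metadata and declare the synonym in a
hidden `index_extra` field that only the offline searcher consults — this
reproduces the real-world situation where PubMed's search index matches
terms that the fetched metadata lacks, which is precisely what the "False"
column flags. A fixed seed reproduces byte-identical corpora; changing the
seed reshuffles surface text but never planned counts or categories.

What the fixtures deliberately do not model: PubMed XML quirks, MEDLINE
field inconsistencies, synonym ambiguity across genes, non-English text,
and the growth of the live database over time. Passing tests therefore
demonstrate that the rules and plumbing are correct, not that any
particular live query today returns the counts a past snapshot did — live
result sets change as the literature grows, which is why the acceptance
checks are phrased as fixture-instantiated worked examples of the rules.

## Known limitations and open points

- Isoform accessions are detected purely syntactically and never fall back
  to the canonical entry; the historical record for such rows (a nonzero
  publication total attached to an excluded isoform) is not reproduced —
  here Category 0 always implies Total 0.
- "False" conflates two readings — a failed synonym+keyword presence check
  and missing scoped metadata; this implementation treats a missing field as
  an automatic check failure, which covers both.
- Category 3 can mean "nothing retrieved" or "everything retrieved failed
  validation"; the comment column distinguishes them.
- No MeSH-aware semantic distances, no relevance ranking within a category,
  no machine-learning classification: the tool is a transparent
  superordinate search whose final judgement stays with the researcher.

## Problem sizes

The shipped demonstration corpus holds 3 queries / 21 records; the property
suites run ~200 randomized corpora of up to ~12 records per query and
brute-force-verify clustering on corpora of ≤6 documents, sizes at which the
independent oracles (token-list matching, frozenset agglomeration) are
exactly enumerable. The whole suite and the acceptance script each run in
well under a minute on one CPU with no network access.
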