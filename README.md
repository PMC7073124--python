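# litprior

Literature-based prioritization of candidate lists from 'omics discovery
experiments.

Proteomics, transcriptomics and genomics screens routinely return hundreds of
significantly regulated genes or proteins, and deciding which of them deserve
follow-up experiments means reviewing the literature for every single one.
`litprior` automates that triage: for each query it expands the gene to all
synonyms recorded in the reviewed (Swiss-Prot) section of UniProt, retrieves
PubMed records in which a synonym co-occurs with a user-chosen contextual
keyword (e.g., *cancer* or *metastasis*), validates each hit, and assigns the
query an evidence tier:

| Category | Meaning |
|---|---|
| 1 | at least one **review** article pairs a synonym with the keyword — well characterized, likely hard to add novelty |
| 2 | original publications exist but no review — verifiable yet under-studied; usually the sweet spot for follow-up |
| 3 | no contextual publication found — potentially novel, but without corroborating literature |
| 0 | no synonyms resolvable: the accession is a splice isoform (`P06753-2`-style suffix) or the entry is unreviewed (TrEMBL) |

Each retrieved record also passes a validation ("False") check: a synonym and
a keyword must genuinely co-occur, whole-word and case-insensitive, in the
scoped fields (title only for the strict search, title or abstract for the
lenient one). Hits whose fetched metadata fails this check stay in the total
but are flagged and excluded from the category evidence.

For every query the retrieved records are additionally clustered by their
MeSH annotations: documents are embedded as binary descriptor incidence
vectors and clustered agglomeratively (average linkage by default, k = 4
clusters) under the cosine distance

    d(A, B) = 1 − (A · B) / (‖A‖ ‖B‖),

and the abstract word frequencies, MeSH descriptor frequencies and
publication-year histogram are tabulated per query. Output is a multi-tab
XLSX workbook (summary first, one tab per query) with a TSV mirror of every
tab.

Retrieval runs either **live** (UniProt REST + NCBI E-utilities, with disk
caching, rate limiting and bounded retries) or **offline** against fixture
corpora in a documented JSON-lines schema; the package ships a deterministic
fixture generator so the whole pipeline is testable without network access.

## Worked example

Generate the demonstration fixture corpus and run the pipeline over it:

```sh
litprior make-fixtures --out fxdemo --seed 0
litprior run --input fxdemo/queries.csv --output fxdemo/report.xlsx \
    --backend fixture --fixture-dir fxdemo
```

`fxdemo/report.Summary.tsv` then contains:

```
UniProtID  GeneName  Synonyms         Keywords  Scope  Total  Category  False
Q15582     TGFBI     TGFBI;BIGH3      cancer    TITLE  18     1         1
P07585     DCN       DCN;SLRR1B;PG40  cancer    TITLE  2      2         0
O15511     ARPC5     ARPC5;ARC16      cancer    TITLE  0      3        0
```

Reading the rows: *TGFBI* retrieved 18 records of which 17 passed validation
and one is a review, so it lands in Category 1 (well characterized in the
cancer context; one record is flagged False because its metadata lacks the
synonym). *DCN* has two validated original articles and no review —
Category 2, a good follow-up candidate. *ARPC5* retrieved nothing —
Category 3. A row with an isoform accession such as `P06753-2` would be
reported as Category 0 with Total 0 and the comment
"no reviewed synonyms (isoform accession)", without any retrieval being
attempted.

The per-query tabs (`report.TGFBI.tsv`, ...) list each record with its
validation flag and MeSH cluster label, followed by the word/MeSH/year
frequency tables.

The same pipeline is available programmatically:

```python
import litprior as lp

spec = lp.demo_spec(seed=0)
corpus = lp.generate_corpus(spec, "fxdemo")
lp.generate_input_sheet(spec, corpus / "queries.csv")
cfg = lp.RunConfig(input_path=corpus / "queries.csv",
                   output_path=corpus / "report.xlsx", fixture_dir=corpus)
lp.run(cfg)
print(lp.read_summary(corpus / "report.xlsx"))
```

For live searches, pass `--backend live --email you@example.org` (an NCBI
API key raises the rate limit; `--cache-dir` makes reruns reproducible).

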