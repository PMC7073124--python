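"""MeSH-based clustering and text summaries of a retrieved record set.

Documents are embedded as binary MeSH-descriptor incidence vectors
(qualifiers stripped, so "Neoplasms/genetics" counts as "Neoplasms") and
clustered agglomeratively under cosine distance, cut at k clusters (default
4). Average linkage is used; the paper trail for binary sparse vocabularies
favours it and it is exposed as an option. Merge ties are broken by the
smallest pmid pair so the clustering is deterministic and invariant under
input-order permutation.

The module also produces the data behind the usual visual summaries: abstract
word frequencies (word-cloud data), MeSH-descriptor frequencies and a
publication-year histogram.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .pubmed_retrieval import PubMedRecord

DEFAULT_CLUSTERS = 4

# Fixed English stopword list shipped with the package so abstract word
# frequencies are reproducible across environments.
STOPWORDS = frozenset(
    """a about above after again against all also although among an and any are as at
    be because been before being below between both but by can cannot could did do
    does doing down during each few for from further had has have having he her here
    hers him his how however i if in into is it its itself just may me might more
    most must my no nor not of off on once only or other our ours out over own per
    same she should so some such than that the their theirs them then there these
    they this those through to too under until up upon us very was we were what when
    where whether which while who whom why will with within without would you your
    yours""".split()
)


@dataclass(frozen=True)
class MeshMatrix:
    """Binary document x MeSH-descriptor incidence matrix."""

    doc_ids: tuple[str, ...]
    vocabulary: tuple[str, ...]
    cells: np.ndarray  # shape (len(doc_ids), len(vocabulary)), values in {0,1}
    excluded: tuple[str, ...] = ()  # pmids with no MeSH terms

    @property
    def empty(self) -> bool:
        return len(self.doc_ids) == 0


@dataclass(frozen=True)
class ClusterAssignment:
    labels: dict[str, int]  # pmid -> cluster id in 1..k
    k: int
    unclustered: tuple[str, ...] = ()


class FrequencyTable:
    """term -> count map with a deterministic descending-count, then
    alphabetical, iteration order."""

    def __init__(self, counts: Counter | dict[str, int] | None = None):
        self._counts = {t: int(c) for t, c in (counts or {}).items() if c >= 1}

    def __len__(self) -> int:
        return len(self._counts)

    def __getitem__(self, term) -> int:
        return self._counts[term]

    def __contains__(self, term) -> bool:
        return term in self._counts

    def __eq__(self, other) -> bool:
        return isinstance(other, FrequencyTable) and self._counts == other._counts

    def items(self) -> list[tuple[str, int]]:
        return sorted(self._counts.items(), key=lambda kv: (-kv[1], str(kv[0])))

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.items())

    def __repr__(self) -> str:
        return f"FrequencyTable({dict(self.items())!r})"


def strip_qualifier(descriptor: str) -> str:
    """Drop a subheading qualifier: "Neoplasms/genetics" -> "Neoplasms"."""
    return descriptor.split("/", 1)[0].strip()


def mesh_matrix(records: Sequence[PubMedRecord]) -> MeshMatrix:
    """Build the binary incidence matrix over the union of descriptors.

    Documents without any MeSH term are excluded from the matrix and listed
    in ``excluded`` (they cannot be placed under cosine distance).
    """
    if not records:
        raise ValueError("mesh_matrix requires at least one record")
    docs: list[tuple[str, set[str]]] = []
    excluded: list[str] = []
    for r in records:
        descs = {strip_qualifier(m) for m in r.mesh_terms if strip_qualifier(m)}
        if descs:
            docs.append((r.pmid, descs))
        else:
            excluded.append(r.pmid)
    vocab = tuple(sorted({d for _, descs in docs for d in descs}))
    index = {d: j for j, d in enumerate(vocab)}
    cells = np.zeros((len(docs), len(vocab)), dtype=np.int8)
    for i, (_, descs) in enumerate(docs):
        for d in descs:
            cells[i, index[d]] = 1
    return MeshMatrix(
        doc_ids=tuple(p for p, _ in docs),
        vocabulary=vocab,
        cells=cells,
        excluded=tuple(excluded),
    )


def cosine_distance(a: Sequence[float] | np.ndarray, b: Sequence[float] | np.ndarray) -> float:
    """1 − (a·b)/(‖a‖‖b‖), clipped to [0, 1] for binary input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have the same length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(np.clip(1.0 - float(a @ b) / (na * nb), 0.0, 1.0))


def _pmid_key(pmid: str):
    return (0, len(pmid), pmid) if pmid.isdigit() else (1, 0, pmid)


def hcluster(
    m: MeshMatrix, k: int = DEFAULT_CLUSTERS, linkage: str = "average"
) -> ClusterAssignment:
    """Agglomerative clustering of the MeSH matrix cut at min(k, n) clusters.

    linkage is "average" (default), "single" or "complete". Ties on the merge
    distance are broken by the smallest pair of cluster-representative pmids,
    making the result deterministic and independent of document input order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if linkage not in ("average", "single", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    n = len(m.doc_ids)
    if n == 0:
        return ClusterAssignment(labels={}, k=k, unclustered=m.excluded)
    # canonical document order removes any input-order dependence
    order = sorted(range(n), key=lambda i: _pmid_key(m.doc_ids[i]))
    ids = [m.doc_ids[i] for i in order]
    if n == 1:
        return ClusterAssignment(labels={ids[0]: 1}, k=k, unclustered=m.excluded)
    dmat = squareform(pdist(m.cells[order].astype(float), metric="cosine"))
    np.clip(dmat, 0.0, 1.0, out=dmat)

    reducer = {"average": np.mean, "single": np.min, "complete": np.max}[linkage]
    clusters: list[list[int]] = [[i] for i in range(len(ids))]
    target = min(k, len(ids))
    while len(clusters) > target:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = float(reducer(dmat[np.ix_(clusters[a], clusters[b])]))
                rep = (_pmid_key(ids[clusters[a][0]]), _pmid_key(ids[clusters[b][0]]))
                cand = (d, rep)
                if best is None or cand < best[0]:
                    best = (cand, a, b)
        _, a, b = best
        merged = sorted(clusters[a] + clusters[b])
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)]
        clusters.append(merged)
        clusters.sort(key=lambda c: _pmid_key(ids[c[0]]))
    labels: dict[str, int] = {}
    for label, cluster in enumerate(
        sorted(clusters, key=lambda c: _pmid_key(ids[c[0]])), start=1
    ):
        for i in cluster:
            labels[ids[i]] = label
    return ClusterAssignment(labels=labels, k=k, unclustered=m.excluded)


def tokenize(text: str, keep_alphanumeric: bool = False) -> list[str]:
    """Lowercase tokens with punctuation and (by default) digits stripped,
    stopwords removed, and tokens shorter than 3 characters dropped."""
    pattern = r"[a-z0-9]+" if keep_alphanumeric else r"[a-z]+"
    return [
        t
        for t in re.findall(pattern, text.lower())
        if len(t) >= 3 and t not in STOPWORDS
    ]


def word_frequencies(
    records: Sequence[PubMedRecord], keep_alphanumeric: bool = False
) -> FrequencyTable:
    """Aggregate word counts over all abstracts (the word-cloud data)."""
    counts: Counter[str] = Counter()
    for r in records:
        counts.update(tokenize(r.abstract, keep_alphanumeric=keep_alphanumeric))
    return FrequencyTable(counts)


def mesh_frequencies(records: Sequence[PubMedRecord]) -> FrequencyTable:
    counts: Counter[str] = Counter()
    for r in records:
        counts.update(
            {strip_qualifier(m) for m in r.mesh_terms if strip_qualifier(m)}
        )
    return FrequencyTable(counts)


def year_histogram(records: Sequence[PubMedRecord]) -> FrequencyTable:
    """Publication-year -> count map; records without a year are omitted."""
    counts: Counter[int] = Counter(r.year for r in records if r.year is not None)
    return FrequencyTable(counts)
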