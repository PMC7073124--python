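"""Validation ("False" check) and category assignment rules."""

import random
from datetime import datetime, timezone

import pytest

from litprior import (
    IdType,
    QueryRow,
    ResultSet,
    Scope,
    SynonymSet,
    SynonymStatus,
    build_query,
    categorize,
    is_review,
    record_matches,
)

from conftest import make_record, oracle_categorize


def _synset(names=("DCN", "decorin"), keywords=("cancer",), scope=Scope.TITLE):
    row = QueryRow("P07585", IdType.UNIPROT, 9606, tuple(keywords), scope)
    return SynonymSet(row, tuple(names), SynonymStatus.OK)


def _resultset(records, syns, scope=Scope.TITLE):
    q = build_query(syns, list(syns.query.keywords), scope)
    return ResultSet(q, tuple(records), datetime.now(timezone.utc), "test")


@pytest.mark.parametrize(
    "types,expected",
    [
        (("Review",), True),
        (("Journal Article",), False),
        (("Systematic Review",), True),
        (("Journal Article", "Review"), True),
        ((), False),
    ],
)
def test_is_review_token_containment(types, expected):
    assert is_review(make_record(types=types)) is expected


class TestRecordMatches:
    def test_title_match(self):
        syns = _synset()
        mr = record_matches(
            make_record(title="Decorin expression in breast cancer"),
            syns,
            ["cancer"],
            Scope.TITLE,
        )
        assert mr.matched
        assert mr.matched_synonym == "decorin"
        assert mr.matched_keyword == "cancer"

    def test_scope_semantics_title_vs_abstract(self):
        syns = _synset()
        rec = make_record(
            title="Decorin structure", abstract="Its role in cancer is debated."
        )
        assert not record_matches(rec, syns, ["cancer"], Scope.TITLE).matched
        assert record_matches(rec, syns, ["cancer"], Scope.TITLE_ABSTRACT).matched

    def test_missing_synonym_is_false(self):
        syns = _synset()
        mr = record_matches(
            make_record(title="Cancer of the thyroid"), syns, ["cancer"], Scope.TITLE
        )
        assert not mr.matched
        assert mr.matched_synonym is None and mr.matched_keyword is None

    def test_whole_word_matching_avoids_substrings(self):
        syns = _synset(names=("CAT",))
        rec = make_record(title="Catalytic mechanisms in cancer")
        assert not record_matches(rec, syns, ["cancer"], Scope.TITLE).matched
        rec2 = make_record(title="CAT activity in cancer")
        assert record_matches(rec2, syns, ["cancer"], Scope.TITLE).matched

    def test_first_matching_terms_in_input_order(self):
        syns = _synset(names=("DCN", "decorin"))
        rec = make_record(title="DCN and decorin in cancer and metastasis")
        mr = record_matches(rec, syns, ["metastasis", "cancer"], Scope.TITLE)
        assert mr.matched_synonym == "DCN"
        assert mr.matched_keyword == "metastasis"


class TestCategorize:
    def test_two_matching_articles_no_review_is_category_2(self):
        syns = _synset()
        records = [
            make_record("1", title="Decorin expression in thyroid cancer"),
            make_record("2", title="DCN loss in cancer tissue"),
        ]
        res = categorize(syns, _resultset(records, syns), ["cancer"], Scope.TITLE)
        assert (res.total, res.category, res.false_count) == (2, 2, 0)

    def test_review_plus_sixteen_articles_one_false_is_category_1(self):
        syns = _synset(names=("TGFBI", "BIGH3"))
        records = [
            make_record("0", title="TGFBI and cancer: a review", types=("Review",))
        ]
        records += [
            make_record(str(i), title=f"TGFBI role in cancer study {i}")
            for i in range(1, 17)
        ]
        records.append(make_record("17", title="Advances in cancer screening"))
        res = categorize(syns, _resultset(records, syns), ["cancer"], Scope.TITLE)
        assert (res.total, res.category, res.false_count) == (18, 1, 1)
        assert res.review_pmids == ("0",)

    def test_no_records_is_category_3(self):
        syns = _synset()
        res = categorize(syns, _resultset([], syns), ["cancer"], Scope.TITLE)
        assert (res.total, res.category, res.false_count) == (0, 3, 0)

    def test_unresolved_synonyms_is_category_0_without_retrieval(self):
        row = QueryRow("P06753-2", IdType.UNIPROT, 9606, ("metastasis",))
        syns = SynonymSet(row, (), SynonymStatus.NO_SYNONYMS_ISOFORM)
        res = categorize(syns, None, ["metastasis"], Scope.TITLE)
        assert (res.total, res.category, res.false_count) == (0, 0, 0)

    def test_all_false_records_is_category_3(self):
        syns = _synset()
        records = [make_record("1", title="Cancer imaging advances")]
        res = categorize(syns, _resultset(records, syns), ["cancer"], Scope.TITLE)
        assert (res.total, res.category, res.false_count) == (1, 3, 1)


def _random_corpus(rng):
    syn_pool = ["DCN", "decorin", "SLRR1B"]
    kw = "cancer"
    records = []
    for i in range(rng.randint(0, 12)):
        has_syn = rng.random() < 0.6
        has_kw = rng.random() < 0.6
        in_title = rng.random() < 0.5
        bits = []
        if has_syn:
            bits.append(rng.choice(syn_pool))
        if has_kw:
            bits.append(kw)
        sentence = " ".join(bits + ["study", "results"])
        title = sentence if in_title else "A molecular profiling study"
        abstract = "" if in_title else sentence
        records.append(
            make_record(
                str(i),
                title=title,
                abstract=abstract,
                types=("Review",) if rng.random() < 0.3 else ("Journal Article",),
            )
        )
    return records


def test_categorize_agrees_with_brute_force_on_random_corpora():
    """Exhaustive/exclusive category assignment equals an independent
    re-derivation of the rules on randomized corpora."""
    rng = random.Random(20240901)
    for trial in range(250):
        scope = rng.choice([Scope.TITLE, Scope.TITLE_ABSTRACT])
        syns = _synset(scope=scope)
        records = _random_corpus(rng)
        res = categorize(syns, _resultset(records, syns, scope), ["cancer"], scope)
        expected = oracle_categorize(records, syns.names, ["cancer"], scope)
        assert (res.total, res.category, res.false_count) == expected
        assert res.category in (1, 2, 3)
        assert res.false_count + len(res.matching_pmids) == res.total


def test_adding_matching_review_forces_category_1():
    rng = random.Random(7)
    syns = _synset()
    for _ in range(30):
        records = _random_corpus(rng)
        review = make_record("999", title="Decorin in cancer: review", types=("Review",))
        res = categorize(
            syns, _resultset(records + [review], syns), ["cancer"], Scope.TITLE
        )
        assert res.category == 1


def test_adding_nonmatching_record_changes_only_total_and_false():
    rng = random.Random(8)
    syns = _synset()
    for _ in range(30):
        records = _random_corpus(rng)
        base = categorize(syns, _resultset(records, syns), ["cancer"], Scope.TITLE)
        extra = make_record("999", title="Unrelated imaging work")
        grown = categorize(
            syns, _resultset(records + [extra], syns), ["cancer"], Scope.TITLE
        )
        assert grown.total == base.total + 1
        assert grown.false_count == base.false_count + 1
        assert grown.matching_pmids == base.matching_pmids
        assert (grown.category == base.category) or (
            base.total == 0 and base.category == 3 and grown.category == 3
        )


def test_scope_monotonicity_on_random_corpora():
    """A TITLE match set is a subset of the TITLE_ABSTRACT match set, so the
    lenient scope never yields a higher category number."""
    rng = random.Random(9)
    for _ in range(60):
        records = _random_corpus(rng)
        syns_t = _synset(scope=Scope.TITLE)
        syns_ta = _synset(scope=Scope.TITLE_ABSTRACT)
        res_t = categorize(
            syns_t, _resultset(records, syns_t), ["cancer"], Scope.TITLE
        )
        res_ta = categorize(
            syns_ta,
            _resultset(records, syns_ta, Scope.TITLE_ABSTRACT),
            ["cancer"],
            Scope.TITLE_ABSTRACT,
        )
        assert set(res_t.matching_pmids) <= set(res_ta.matching_pmids)
        assert res_ta.category <= res_t.category
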