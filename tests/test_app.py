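"""Input-sheet parsing and end-to-end batch runs over fixture corpora."""

import pandas as pd
import pytest

from litprior import (
    BackendKind,
    IdType,
    RunConfig,
    Scope,
    demo_spec,
    generate_corpus,
    generate_input_sheet,
    parse_input_sheet,
    read_summary,
    run,
)
from litprior.app import InputError


def _write_sheet(path, rows):
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


class TestParseInputSheet:
    def test_basic_row(self, tmp_path):
        p = _write_sheet(
            tmp_path / "q.csv",
            [{"Identifier": "P07585", "IdType": "UNIPROT", "TaxonomyID": 9606,
              "Keywords": "cancer", "TitleOnly": "TRUE"}],
        )
        rows, rejects = parse_input_sheet(p)
        assert rejects == []
        assert rows[0].identifier == "P07585"
        assert rows[0].scope is Scope.TITLE

    def test_semicolon_keywords_split(self, tmp_path):
        p = _write_sheet(
            tmp_path / "q.csv",
            [{"Identifier": "P07585", "IdType": "UNIPROT", "TaxonomyID": 9606,
              "Keywords": "cancer;metastasis", "TitleOnly": "FALSE"}],
        )
        rows, _ = parse_input_sheet(p)
        assert rows[0].keywords == ("cancer", "metastasis")
        assert rows[0].scope is Scope.TITLE_ABSTRACT

    def test_malformed_taxonomy_rejected_with_reason(self, tmp_path):
        p = _write_sheet(
            tmp_path / "q.csv",
            [{"Identifier": "P07585", "IdType": "UNIPROT", "TaxonomyID": "human",
              "Keywords": "cancer", "TitleOnly": "TRUE"}],
        )
        rows, rejects = parse_input_sheet(p)
        assert rows == []
        assert len(rejects) == 1 and rejects[0][0] == 0

    def test_missing_mandatory_column_fatal(self, tmp_path):
        p = _write_sheet(tmp_path / "q.csv", [{"Identifier": "P07585"}])
        with pytest.raises(InputError, match="IdType"):
            parse_input_sheet(p)

    def test_gene_rows_and_date_range(self, tmp_path):
        p = _write_sheet(
            tmp_path / "q.csv",
            [{"Identifier": "DCN", "IdType": "GENE", "TaxonomyID": 9606,
              "Keywords": "cancer", "TitleOnly": "TRUE",
              "DateStart": "2000-01-01", "DateEnd": "2015-12-31"}],
        )
        rows, _ = parse_input_sheet(p)
        assert rows[0].id_type is IdType.GENE
        assert rows[0].date_range is not None

    def test_xlsx_input_supported(self, tmp_path):
        p = tmp_path / "q.xlsx"
        pd.DataFrame(
            [{"Identifier": "P07585", "IdType": "UNIPROT", "TaxonomyID": 9606,
              "Keywords": "cancer", "TitleOnly": "TRUE"}]
        ).to_excel(p, index=False)
        rows, rejects = parse_input_sheet(p)
        assert rejects == [] and rows[0].identifier == "P07585"


@pytest.fixture
def fixture_run(tmp_path):
    spec = demo_spec(seed=13)
    corpus = generate_corpus(spec, tmp_path / "corpus")
    generate_input_sheet(spec, corpus / "queries.csv")

    def _run(out_name="report.xlsx", **overrides):
        cfg = RunConfig(
            input_path=corpus / "queries.csv",
            output_path=tmp_path / out_name,
            backend=BackendKind.FIXTURE,
            fixture_dir=corpus,
            **overrides,
        )
        return run(cfg), tmp_path / out_name

    return _run, corpus


class TestRun:
    def test_fixture_run_summary_rows(self, fixture_run):
        _run, _ = fixture_run
        code, out = _run()
        assert code == 0
        rows = read_summary(out)
        by_id = {r.uniprot_id: r for r in rows}
        assert (by_id["Q15582"].total, by_id["Q15582"].category,
                by_id["Q15582"].false_count) == (18, 1, 1)
        assert (by_id["P07585"].total, by_id["P07585"].category) == (2, 2)
        assert (by_id["O15511"].total, by_id["O15511"].category) == (0, 3)

    def test_isoform_row_is_category_0_without_retrieval(self, fixture_run, tmp_path):
        _run, corpus = fixture_run
        spec = demo_spec(seed=13)
        generate_input_sheet(
            spec, corpus / "queries.csv",
            extra_rows=[{"Identifier": "P06753-2", "IdType": "UNIPROT",
                         "TaxonomyID": 9606, "Keywords": "metastasis",
                         "TitleOnly": True}],
        )
        code, out = _run("with_isoform.xlsx")
        assert code == 0
        iso = [r for r in read_summary(out) if r.uniprot_id == "P06753-2"][0]
        assert (iso.total, iso.category, iso.false_count) == (0, 0, 0)
        assert "isoform" in iso.comment

    def test_repeat_runs_byte_identical_tsvs(self, fixture_run, tmp_path):
        _run, _ = fixture_run
        _run("a.xlsx")
        _run("b.xlsx")
        for suffix in ("Summary", "TGFBI", "DCN", "ARPC5"):
            a = (tmp_path / f"a.{suffix}.tsv").read_bytes()
            b = (tmp_path / f"b.{suffix}.tsv").read_bytes()
            assert a == b
        assert read_summary(tmp_path / "a.xlsx") == read_summary(tmp_path / "b.xlsx")

    def test_empty_input_table_exits_clean(self, tmp_path):
        from litprior import CorpusSpec

        spec = CorpusSpec(seed=0, plans=())
        corpus = generate_corpus(spec, tmp_path / "c")
        generate_input_sheet(spec, corpus / "queries.csv")
        cfg = RunConfig(
            input_path=corpus / "queries.csv",
            output_path=tmp_path / "r.xlsx",
            fixture_dir=corpus,
        )
        assert run(cfg) == 0
        assert read_summary(tmp_path / "r.xlsx") == []

    def test_bad_row_isolated_from_good_rows(self, tmp_path):
        spec = demo_spec(seed=13)
        corpus = generate_corpus(spec, tmp_path / "c")
        pd.DataFrame(
            [
                {"Identifier": "Q15582", "IdType": "UNIPROT", "TaxonomyID": 9606,
                 "Keywords": "cancer", "TitleOnly": "TRUE"},
                {"Identifier": "XXXXX", "IdType": "UNIPROT", "TaxonomyID": "bogus",
                 "Keywords": "cancer", "TitleOnly": "TRUE"},
            ]
        ).to_csv(corpus / "queries.csv", index=False)
        cfg = RunConfig(
            input_path=corpus / "queries.csv",
            output_path=tmp_path / "r.xlsx",
            fixture_dir=corpus,
        )
        assert run(cfg) == 1  # rejected row -> nonzero, but good row processed
        rows = read_summary(tmp_path / "r.xlsx")
        assert rows[0].uniprot_id == "Q15582" and rows[0].total == 18


def test_runconfig_validation(tmp_path):
    with pytest.raises(ValueError):
        RunConfig(input_path=tmp_path, output_path=tmp_path,
                  backend=BackendKind.LIVE)
    with pytest.raises(ValueError):
        RunConfig(input_path=tmp_path, output_path=tmp_path,
                  backend=BackendKind.FIXTURE, fixture_dir=None)
    with pytest.raises(ValueError):
        RunConfig(input_path=tmp_path, output_path=tmp_path,
                  fixture_dir=tmp_path, clusters=0)


def test_cli_make_fixtures_and_run(tmp_path):
    from click.testing import CliRunner

    from litprior.app import main

    runner = CliRunner()
    res = runner.invoke(main, ["make-fixtures", "--out", str(tmp_path / "fx"), "--seed", "3"])
    assert res.exit_code == 0, res.output
    res = runner.invoke(
        main,
        ["run", "--input", str(tmp_path / "fx" / "queries.csv"),
         "--output", str(tmp_path / "r.xlsx"),
         "--backend", "fixture", "--fixture-dir", str(tmp_path / "fx")],
    )
    assert res.exit_code == 0, res.output
    assert (tmp_path / "r.xlsx").exists()
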