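"""Logs, summaries, and the static site: content contracts and determinism."""

from __future__ import annotations

import pytest
from lxml import html as lxml_html

from mwstatus.comparator import ComparisonResult
from mwstatus.fixtures import generate_corpus
from mwstatus.harvester import SourceConfig
from mwstatus.model import ComparisonStatus, FileStatus, SourceFormat
from mwstatus.pipeline import run_validation
from mwstatus.reporting import (
    AnalysisRecord,
    ValidationLog,
    build_site,
    render_validation_log,
    summarize,
)

TS = "2026-09-01T00:00:00Z"


def make_log(status=FileStatus.PASSING, issues=(), fmt=SourceFormat.TEXT):
    return ValidationLog(
        run_timestamp=TS,
        validator_version="1.0.0",
        spec_version_used="1.5",
        selection_reason="header VERSION 1.5 matched a registered schema",
        study_id="ST000001",
        analysis_id="AN000001",
        format=fmt,
        status=status,
        issues=list(issues),
    )


def make_record(analysis_id, study_id="ST000001", text=FileStatus.PASSING,
                jsn=FileStatus.PASSING, comp=ComparisonStatus.CONSISTENT):
    return AnalysisRecord(
        study_id=study_id,
        analysis_id=analysis_id,
        text_status=text,
        json_status=jsn,
        comparison=ComparisonResult(comp),
    )


class TestValidationLog:
    def test_passing_log_has_identity_and_zero_errors(self):
        text = render_validation_log(make_log())
        assert "AN000001" in text
        assert "Number of errors: 0" in text

    def test_metadata_groups_appear_in_order(self):
        """Run conditions come first, then file identity, then the errors."""
        text = render_validation_log(make_log())
        assert (
            text.index("Generated on")
            < text.index("Schema version")
            < text.index("Study ID")
            < text.index("File status")
            < text.index("Number of errors")
        )

    def test_three_issues_render_as_count_plus_three_lines(self):
        issues = [f"SCHEMA STUDY:{k} - required key {k} is absent" for k in "ABC"]
        text = render_validation_log(
            make_log(FileStatus.VALIDATION_ERROR, issues)
        )
        assert "Number of errors: 3" in text
        assert sum(line.startswith(" - ") for line in text.splitlines()) == 3

    def test_missing_file_still_gets_a_log(self):
        text = render_validation_log(make_log(FileStatus.MISSING))
        assert "AN000001" in text
        assert "could not be retrieved" in text

    def test_passing_log_rejects_issues(self):
        with pytest.raises(ValueError):
            make_log(FileStatus.PASSING, ["an issue"])

    def test_deterministic_given_fixed_timestamp(self):
        assert render_validation_log(make_log()) == render_validation_log(make_log())


class TestSummarize:
    def test_empty_corpus(self):
        summary = summarize([])
        assert summary.total_analyses == 0
        assert all(v == 0 for counts in summary.per_format.values() for v in counts.values())

    def test_counts_partition_the_corpus(self):
        records = [
            make_record("AN000001"),
            make_record("AN000002", text=FileStatus.MISSING, comp=ComparisonStatus.NOT_CHECKED),
            make_record("AN000003", jsn=FileStatus.VALIDATION_ERROR, comp=ComparisonStatus.INCONSISTENT),
        ]
        summary = summarize(records)
        for fmt in SourceFormat:
            assert sum(summary.per_format[fmt].values()) == summary.total_analyses
        assert sum(summary.comparison.values()) == summary.total_analyses

    def test_duplicate_analysis_ids_are_a_pipeline_error(self):
        with pytest.raises(ValueError):
            summarize([make_record("AN000001"), make_record("AN000001")])

    def test_record_invariant_comparison_must_be_not_checked(self):
        with pytest.raises(ValueError):
            make_record("AN000001", text=FileStatus.PARSING_ERROR,
                        comp=ComparisonStatus.CONSISTENT)


@pytest.fixture(scope="module")
def site(tmp_path_factory):
    """A validated 3-study corpus with its rendered site and logs."""
    tmp = tmp_path_factory.mktemp("site-corpus")
    generate_corpus(seed=21, n_studies=3, output_dir=tmp / "corpus", n_analyses=12)
    records, summary = run_validation(
        SourceConfig.for_directory(tmp / "corpus"),
        out_dir=tmp / "results",
        timestamp=TS,
    )
    build_site(records, summary, tmp / "site", generated_at=TS)
    return tmp, records, summary


class TestSite:
    def test_regeneration_is_byte_identical(self, site, tmp_path):
        tmp, records, summary = site
        build_site(records, summary, tmp_path / "again", generated_at=TS)
        originals = sorted((tmp / "site").rglob("*.*"))
        copies = sorted((tmp_path / "again").rglob("*.*"))
        assert [p.relative_to(tmp / "site") for p in originals] == [
            p.relative_to(tmp_path / "again") for p in copies
        ]
        for a, b in zip(originals, copies):
            assert a.read_bytes() == b.read_bytes()

    def test_index_links_every_study_page(self, site):
        tmp, records, _ = site
        doc = lxml_html.fromstring((tmp / "site" / "index.html").read_text())
        hrefs = doc.xpath('//table[@id="studies"]//a/@href')
        studies = {r.study_id for r in records}
        assert len(hrefs) == len(studies)
        for study_id in studies:
            assert f"studies/{study_id}.html" in hrefs
            assert (tmp / "site" / "studies" / f"{study_id}.html").is_file()

    def test_index_summary_table_equals_summarize_output(self, site):
        tmp, _, summary = site
        doc = lxml_html.fromstring((tmp / "site" / "index.html").read_text())
        rows = doc.xpath('//table[@id="status-summary"]/tr')[1:]
        parsed = {
            row[0].text_content(): (int(row[1].text_content()), int(row[2].text_content()))
            for row in rows
        }
        for status in FileStatus:
            assert parsed[status.value] == (
                summary.per_format[SourceFormat.TEXT][status],
                summary.per_format[SourceFormat.JSON][status],
            )
        comp_rows = doc.xpath('//table[@id="comparison-summary"]/tr')[1:]
        comp = {row[0].text_content(): int(row[1].text_content()) for row in comp_rows}
        for status in ComparisonStatus:
            assert comp[status.value] == summary.comparison[status]

    def test_every_badge_agrees_with_its_log_file(self, site):
        """Each status badge in the HTML equals the status rendered into the
        corresponding plain-text validation log."""
        tmp, records, _ = site
        logs_dir = tmp / "results" / "logs"
        checked = 0
        for record in records:
            page = tmp / "site" / "studies" / f"{record.study_id}.html"
            doc = lxml_html.fromstring(page.read_text())
            row = doc.xpath(
                f'//tr[td[@class="analysis-id"]="{record.analysis_id}"]'
            )[0]
            for css, fmt in (("text-status", "txt"), ("json-status", "json")):
                badge = row.xpath(f'td[@class="{css}"]/span/text()')[0]
                log_text = (logs_dir / f"{record.analysis_id}_{fmt}.log").read_text()
                assert f"File status: {badge}" in log_text
                checked += 1
            comp_badge = row.xpath('td[@class="comparison-status"]/span/text()')[0]
            comp_log = (logs_dir / f"{record.analysis_id}_comparison.log").read_text()
            assert f"Comparison status: {comp_badge}" in comp_log
        assert checked == 2 * len(records)

    def test_analysis_rows_across_pages_equal_total(self, site):
        tmp, records, summary = site
        n_rows = 0
        for page in (tmp / "site" / "studies").glob("*.html"):
            doc = lxml_html.fromstring(page.read_text())
            n_rows += len(doc.xpath('//table[@id="analyses"]/tr')) - 1
        assert n_rows == summary.total_analyses

    def test_clean_study_page_has_no_error_badges(self, tmp_path):
        records = [make_record("AN000001"), make_record("AN000002")]
        summary = summarize(records)
        build_site(records, summary, tmp_path, generated_at=TS)
        doc = lxml_html.fromstring((tmp_path / "studies" / "ST000001.html").read_text())
        classes = " ".join(doc.xpath("//span/@class"))
        assert "st-parsing-error" not in classes
        assert "st-validation-error" not in classes
        assert "st-missing" not in classes
        assert "st-inconsistent" not in classes
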