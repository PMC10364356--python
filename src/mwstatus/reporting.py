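"""Validation/comparison logs, corpus summaries, and the static status site.

Every artifact here is a pure function of its inputs plus an injected
timestamp, so regenerating with unchanged inputs and a fixed clock yields
byte-identical output — a property the tests rely on and that keeps the
published site diff-friendly.

A validation log always exists, even for blank or missing files: it carries
three metadata groups in order — when/under what conditions validation ran,
which file it identifies, and the error count followed by itemized issues.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from string import Template

from . import __version__
from .comparator import ComparisonResult, Discrepancy, DiscrepancyKind
from .model import ComparisonStatus, FileStatus, SourceFormat


@dataclass
class ValidationLog:
    """Structured record of one validation run over one (analysis, format)."""

    run_timestamp: str
    validator_version: str
    spec_version_used: str
    selection_reason: str
    study_id: str
    analysis_id: str
    format: SourceFormat
    status: FileStatus
    issues: list[str] = field(default_factory=list)

    @property
    def error_count(self) -> int:
        return len(self.issues)

    def __post_init__(self) -> None:
        if self.status in (FileStatus.PASSING, FileStatus.MISSING) and self.issues:
            raise ValueError(f"{self.status.value} log cannot carry issues")


def render_validation_log(log: ValidationLog) -> str:
    lines = [
        "mwTab validation log",
        "====================",
        f"Generated on:      {log.run_timestamp}",
        f"Validator version: mwstatus {log.validator_version}",
        f"Schema version:    {log.spec_version_used}",
        f"Schema selection:  {log.selection_reason}",
        "",
        f"Study ID:    {log.study_id}",
        f"Analysis ID: {log.analysis_id}",
        f"File format: {log.format.value}",
        f"File status: {log.status.value}",
        "",
        f"Number of errors: {log.error_count}",
    ]
    if log.status is FileStatus.MISSING:
        lines.append("File could not be retrieved from the data source.")
    for issue in log.issues:
        lines.append(f" - {issue}")
    return "\n".join(lines) + "\n"


def render_comparison_log(
    run_timestamp: str,
    study_id: str,
    analysis_id: str,
    result: ComparisonResult,
) -> str:
    lines = [
        "mwTab text/JSON comparison log",
        "==============================",
        f"Generated on: {run_timestamp}",
        f"Comparator version: mwstatus {__version__}",
        "",
        f"Study ID:    {study_id}",
        f"Analysis ID: {analysis_id}",
        f"Comparison status: {result.status.value}",
        "",
        f"Number of discrepancies: {len(result.discrepancies)}",
    ]
    if result.reason:
        lines.append(f"Not checked because: {result.reason}")
    for d in result.discrepancies:
        lines.append(f" - {d}")
    return "\n".join(lines) + "\n"


@dataclass
class AnalysisRecord:
    """Per-analysis rollup: both format statuses plus the comparison outcome."""

    study_id: str
    analysis_id: str
    text_status: FileStatus
    json_status: FileStatus
    comparison: ComparisonResult
    log_paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        blocked = {FileStatus.MISSING, FileStatus.PARSING_ERROR}
        if (
            self.text_status in blocked or self.json_status in blocked
        ) and self.comparison.status is not ComparisonStatus.NOT_CHECKED:
            raise ValueError(
                "comparison must be NOT_CHECKED when either format is "
                "missing or unparsable"
            )

    def to_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "analysis_id": self.analysis_id,
            "text_status": self.text_status.value,
            "json_status": self.json_status.value,
            "comparison": {
                "status": self.comparison.status.value,
                "reason": self.comparison.reason,
                "discrepancies": [
                    {
                        "path": d.path,
                        "kind": d.kind.name,
                        "text_value": d.text_value,
                        "json_value": d.json_value,
                    }
                    for d in self.comparison.discrepancies
                ],
            },
            "log_paths": dict(self.log_paths),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisRecord":
        comp = data["comparison"]
        return cls(
            study_id=data["study_id"],
            analysis_id=data["analysis_id"],
            text_status=FileStatus(data["text_status"]),
            json_status=FileStatus(data["json_status"]),
            comparison=ComparisonResult(
                status=ComparisonStatus(comp["status"]),
                reason=comp.get("reason"),
                discrepancies=[
                    Discrepancy(
                        path=d["path"],
                        kind=DiscrepancyKind[d["kind"]],
                        text_value=d.get("text_value"),
                        json_value=d.get("json_value"),
                    )
                    for d in comp.get("discrepancies", [])
                ],
            ),
            log_paths=dict(data.get("log_paths", {})),
        )


@dataclass
class StatusSummary:
    """Corpus-level tallies: per-format status counts and comparison counts."""

    per_format: dict[SourceFormat, dict[FileStatus, int]]
    comparison: dict[ComparisonStatus, int]
    total_analyses: int


def summarize(records: list[AnalysisRecord]) -> StatusSummary:
    """Tally statuses over the corpus; each analysis must appear exactly once."""
    seen: set[str] = set()
    per_format = {
        fmt: {status: 0 for status in FileStatus} for fmt in SourceFormat
    }
    comparison = {status: 0 for status in ComparisonStatus}
    for record in records:
        if record.analysis_id in seen:
            raise ValueError(f"duplicate analysis id {record.analysis_id}")
        seen.add(record.analysis_id)
        per_format[SourceFormat.TEXT][record.text_status] += 1
        per_format[SourceFormat.JSON][record.json_status] += 1
        comparison[record.comparison.status] += 1
    return StatusSummary(per_format, comparison, len(records))


# --------------------------------------------------------------------------
# static site generation

_PAGE = Template(
    """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>$title</title>
<link rel="stylesheet" href="$css_href">
</head>
<body>
$body
<footer>Generated on $generated_at by mwstatus $version.</footer>
</body>
</html>
"""
)


def _css_class(status: FileStatus | ComparisonStatus) -> str:
    return "st-" + status.value.lower().replace(" ", "-")


def _badge(status: FileStatus | ComparisonStatus) -> str:
    return (
        f'<span class="badge {_css_class(status)}">{html.escape(status.value)}</span>'
    )


def _summary_tables(summary: StatusSummary) -> str:
    rows = "\n".join(
        "<tr><td>{status}</td><td>{txt}</td><td>{js}</td></tr>".format(
            status=html.escape(status.value),
            txt=summary.per_format[SourceFormat.TEXT][status],
            js=summary.per_format[SourceFormat.JSON][status],
        )
        for status in FileStatus
    )
    comp_rows = "\n".join(
        f"<tr><td>{html.escape(status.value)}</td><td>{summary.comparison[status]}</td></tr>"
        for status in ComparisonStatus
    )
    return (
        "<h2>File status per format</h2>\n"
        '<table id="status-summary">\n'
        "<tr><th>Status \\ file format</th><th>mwTab</th><th>JSON</th></tr>\n"
        f"{rows}\n</table>\n"
        "<h2>Text/JSON comparison</h2>\n"
        '<table id="comparison-summary">\n'
        "<tr><th>Status</th><th>Count</th></tr>\n"
        f"{comp_rows}\n</table>\n"
    )


def build_site(
    records: list[AnalysisRecord],
    summary: StatusSummary,
    output_dir: str | Path,
    generated_at: str,
    logs_href: str = "../logs",
) -> list[Path]:
    """Render the status site: one index page plus one page per study.

    Output is a pure function of (records, summary, generated_at); rerunning
    with identical inputs produces byte-identical files.  ``logs_href`` is
    the href prefix, relative to a study page, under which the plain-text
    logs are published.
    """
    out = Path(output_dir)
    (out / "studies").mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    css = resources.files("mwstatus.templates").joinpath("style.css").read_text("utf-8")
    css_path = out / "style.css"
    css_path.write_text(css, encoding="utf-8")
    written.append(css_path)

    by_study: dict[str, list[AnalysisRecord]] = {}
    for record in records:
        by_study.setdefault(record.study_id, []).append(record)

    study_rows = []
    for study_id in sorted(by_study):
        study_records = sorted(by_study[study_id], key=lambda r: r.analysis_id)
        n_clean = sum(
            1
            for r in study_records
            if r.text_status is FileStatus.PASSING
            and r.json_status is FileStatus.PASSING
            and r.comparison.status is ComparisonStatus.CONSISTENT
        )
        study_rows.append(
            f'<tr><td><a href="studies/{study_id}.html">{study_id}</a></td>'
            f"<td>{len(study_records)}</td><td>{n_clean}</td></tr>"
        )
        page_path = out / "studies" / f"{study_id}.html"
        page_path.write_text(
            _study_page(study_id, study_records, generated_at, logs_href),
            encoding="utf-8",
        )
        written.append(page_path)

    body = (
        "<h1>Metabolomics Workbench file status</h1>\n"
        f"<p>Validation results for {summary.total_analyses} analyses in "
        f"{len(by_study)} studies.</p>\n"
        + _summary_tables(summary)
        + "<h2>Studies</h2>\n"
        '<table id="studies">\n'
        "<tr><th>Study</th><th>Analyses</th><th>Fully clean</th></tr>\n"
        + "\n".join(study_rows)
        + "\n</table>\n"
    )
    index_path = out / "index.html"
    index_path.write_text(
        _PAGE.substitute(
            title="Metabolomics Workbench file status",
            css_href="style.css",
            body=body,
            generated_at=html.escape(generated_at),
            version=__version__,
        ),
        encoding="utf-8",
    )
    written.append(index_path)
    return written


def _study_page(
    study_id: str,
    records: list[AnalysisRecord],
    generated_at: str,
    logs_href: str,
) -> str:
    rows = []
    for r in records:
        links = []
        for label, key in (("text log", "text"), ("JSON log", "json"), ("comparison", "comparison")):
            name = r.log_paths.get(key)
            if name:
                links.append(f'<a href="{logs_href}/{html.escape(name)}">{label}</a>')
        rows.append(
            "<tr>"
            f'<td class="analysis-id">{r.analysis_id}</td>'
            f'<td class="text-status">{_badge(r.text_status)}</td>'
            f'<td class="json-status">{_badge(r.json_status)}</td>'
            f'<td class="comparison-status">{_badge(r.comparison.status)}</td>'
            f"<td>{' | '.join(links)}</td>"
            "</tr>"
        )
    body = (
        f"<h1>Study {study_id}</h1>\n"
        '<p><a href="../index.html">Back to index</a></p>\n'
        '<table id="analyses">\n'
        "<tr><th>Analysis</th><th>mwTab</th><th>JSON</th>"
        "<th>Comparison</th><th>Logs</th></tr>\n" + "\n".join(rows) + "\n</table>\n"
    )
    return _PAGE.substitute(
        title=f"Study {study_id} file status",
        css_href="../style.css",
        body=body,
        generated_at=html.escape(generated_at),
        version=__version__,
    )
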