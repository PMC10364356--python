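"""End-to-end orchestration: harvest -> parse -> validate -> compare -> report.

``run_validation`` drives one full pass over a source (REST mirror or local
directory), producing per-file validation logs, per-analysis comparison
logs, a machine-readable ``records.json`` and a corpus summary.  The status
site is rendered separately (``mwstatus.reporting.build_site``) from those
records, so validation and site generation can run as independent stages.

An optional content-hash cache lets repeated runs skip re-validating
analyses whose raw bytes are unchanged — useful when mirroring a large
repository on a schedule.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .comparator import compare
from .harvester import FetchResult, RateLimiter, SourceConfig, harvest
from .model import (
    FetchOutcome,
    FileStatus,
    MWTabFile,
    ParseFailure,
    SourceFormat,
)
from .mwtab_io import parse_mwtab_json, parse_mwtab_text
from .reporting import (
    AnalysisRecord,
    StatusSummary,
    ValidationLog,
    render_comparison_log,
    render_validation_log,
    summarize,
)
from .schema_validator import (
    DEFAULT_VERSION,
    SchemaSpec,
    classify_status,
    load_registry,
    select_schema,
    validate_file,
)

logger = logging.getLogger(__name__)

_PARSERS = {
    SourceFormat.TEXT: parse_mwtab_text,
    SourceFormat.JSON: parse_mwtab_json,
}


def _now_iso() -> str:
    return datetime.datetime.now(datetime.timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def process_analysis(
    study_id: str,
    analysis_id: str,
    results: dict[SourceFormat, FetchResult],
    registry: dict[str, SchemaSpec],
    default_version: str = DEFAULT_VERSION,
    timestamp: str | None = None,
) -> tuple[AnalysisRecord, dict[str, str]]:
    """Validate both formats of one analysis and compare them.

    Returns the rollup record plus the rendered plain-text logs keyed by
    file name.
    """
    timestamp = timestamp or _now_iso()
    statuses: dict[SourceFormat, FileStatus] = {}
    parses: dict[SourceFormat, MWTabFile | ParseFailure | None] = {}
    logs: dict[str, str] = {}
    log_paths: dict[str, str] = {}

    for fmt in (SourceFormat.TEXT, SourceFormat.JSON):
        result = results[fmt]
        spec_version_used = default_version
        selection_reason = "schema not applied"
        issues: list[str] = []
        if result.outcome is FetchOutcome.ABSENT:
            parses[fmt] = None
            status = classify_status(FetchOutcome.ABSENT, None, None)
        else:
            parsed = _PARSERS[fmt](result.content)
            parses[fmt] = parsed
            if isinstance(parsed, ParseFailure):
                status = classify_status(FetchOutcome.RETRIEVED, parsed, None)
                where = f" ({parsed.location})" if parsed.location else ""
                issues = [f"{parsed.category}: {parsed.message}{where}"]
            else:
                selection = select_schema(parsed, registry, default_version)
                spec_version_used = selection.spec.version
                selection_reason = selection.reason
                found = selection.issues + validate_file(parsed, selection.spec)
                status = classify_status(FetchOutcome.RETRIEVED, parsed, found)
                issues = [str(i) for i in found]
        statuses[fmt] = status
        log = ValidationLog(
            run_timestamp=timestamp,
            validator_version=__version__,
            spec_version_used=spec_version_used,
            selection_reason=selection_reason,
            study_id=study_id,
            analysis_id=analysis_id,
            format=fmt,
            status=status,
            issues=issues,
        )
        key = "text" if fmt is SourceFormat.TEXT else "json"
        name = f"{analysis_id}_{fmt.value}.log"
        logs[name] = render_validation_log(log)
        log_paths[key] = name

    comparison = compare(parses[SourceFormat.TEXT], parses[SourceFormat.JSON])
    comp_name = f"{analysis_id}_comparison.log"
    logs[comp_name] = render_comparison_log(timestamp, study_id, analysis_id, comparison)
    log_paths["comparison"] = comp_name

    record = AnalysisRecord(
        study_id=study_id,
        analysis_id=analysis_id,
        text_status=statuses[SourceFormat.TEXT],
        json_status=statuses[SourceFormat.JSON],
        comparison=comparison,
        log_paths=log_paths,
    )
    return record, logs


def _content_hash(results: dict[SourceFormat, FetchResult]) -> str:
    h = hashlib.sha256()
    for fmt in (SourceFormat.TEXT, SourceFormat.JSON):
        result = results[fmt]
        h.update(b"\x00absent" if result.content is None else b"\x01" + result.content)
    return h.hexdigest()


def run_validation(
    source: SourceConfig,
    out_dir: str | Path | None = None,
    default_version: str = DEFAULT_VERSION,
    transport=None,
    limiter: RateLimiter | None = None,
    save_files: bool = False,
    timestamp: str | None = None,
    cache_path: str | Path | None = None,
) -> tuple[list[AnalysisRecord], StatusSummary]:
    """Run the full validate-and-compare stage over a source.

    With ``out_dir`` set, writes ``logs/*.log``, ``records.json`` and
    ``summary.json`` there (plus the raw files under ``files/`` when
    ``save_files``).  With ``cache_path`` set, unchanged analyses (by
    content hash of their raw byte pair) reuse their previous record and
    skip re-validation.
    """
    timestamp = timestamp or _now_iso()
    registry = load_registry()
    out = Path(out_dir) if out_dir is not None else None
    logs_dir = None
    if out is not None:
        logs_dir = out / "logs"
        logs_dir.mkdir(parents=True, exist_ok=True)

    cache: dict = {}
    if cache_path is not None and Path(cache_path).is_file():
        cache = json.loads(Path(cache_path).read_text(encoding="utf-8"))

    sink = out / "files" if (out is not None and save_files) else None
    records: list[AnalysisRecord] = []
    new_cache: dict = {}
    for study_id, analysis_id, results in harvest(
        source, sink=sink, transport=transport, limiter=limiter
    ):
        digest = _content_hash(results)
        cached = cache.get(analysis_id)
        if cached is not None and cached.get("sha256") == digest:
            record = AnalysisRecord.from_dict(cached["record"])
            logs = {}
            logger.debug("cache hit for %s; skipping re-validation", analysis_id)
        else:
            record, logs = process_analysis(
                study_id,
                analysis_id,
                results,
                registry,
                default_version=default_version,
                timestamp=timestamp,
            )
        records.append(record)
        new_cache[analysis_id] = {"sha256": digest, "record": record.to_dict()}
        if logs_dir is not None:
            for name, text in logs.items():
                (logs_dir / name).write_text(text, encoding="utf-8")

    summary = summarize(records)
    if out is not None:
        (out / "records.json").write_text(
            json.dumps([r.to_dict() for r in records], indent=2) + "\n",
            encoding="utf-8",
        )
        (out / "summary.json").write_text(
            json.dumps(summary_to_dict(summary), indent=2) + "\n", encoding="utf-8"
        )
    if cache_path is not None:
        Path(cache_path).write_text(
            json.dumps(new_cache, indent=2) + "\n", encoding="utf-8"
        )
    return records, summary


def summary_to_dict(summary: StatusSummary) -> dict:
    return {
        "total_analyses": summary.total_analyses,
        "per_format": {
            fmt.value: {st.value: n for st, n in counts.items()}
            for fmt, counts in summary.per_format.items()
        },
        "comparison": {st.value: n for st, n in summary.comparison.items()},
    }


def load_records(results_dir: str | Path) -> list[AnalysisRecord]:
    """Read back the records a previous ``run_validation`` wrote."""
    path = Path(results_dir) / "records.json"
    data = json.loads(path.read_text(encoding="utf-8"))
    return [AnalysisRecord.from_dict(d) for d in data]


def check_against_manifest(
    records: list[AnalysisRecord], manifest
) -> list[str]:
    """Misclassification report against a fixture corpus's ground truth.

    Returns one line per disagreement (empty list = perfect recovery):
    the acceptance oracle for the synthetic corpus.
    """
    problems: list[str] = []
    by_id = {r.analysis_id: r for r in records}
    for analysis_id, entry in sorted(manifest.entries.items()):
        record = by_id.get(analysis_id)
        if record is None:
            problems.append(f"{analysis_id}: not processed")
            continue
        if record.text_status is not entry.expected_text_status:
            problems.append(
                f"{analysis_id}: text {record.text_status.value!r} != "
                f"expected {entry.expected_text_status.value!r}"
            )
        if record.json_status is not entry.expected_json_status:
            problems.append(
                f"{analysis_id}: json {record.json_status.value!r} != "
                f"expected {entry.expected_json_status.value!r}"
            )
        if record.comparison.status is not entry.expected_comparison:
            problems.append(
                f"{analysis_id}: comparison {record.comparison.status.value!r} != "
                f"expected {entry.expected_comparison.value!r}"
            )
    extra = set(by_id) - set(manifest.entries)
    for analysis_id in sorted(extra):
        problems.append(f"{analysis_id}: processed but not in manifest")
    return problems
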