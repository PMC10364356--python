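"""Cross-format consistency check between one analysis's text and JSON files.

The two serializations of an analysis derive from a single deposition, so any
difference between them points at the repository's conversion software.
Comparison is therefore exact string comparison after trimming leading and
trailing whitespace — no numeric tolerance: formatting drift is itself an
inconsistency worth reporting.  Key *order* differences are not discrepancies
(order is serialization detail); presence and value differences are.

A pair can only be compared when both sides parsed; if either format is
missing or unparsable the result is NOT_CHECKED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .model import ComparisonStatus, MWTabFile, ParseFailure, SectionKind


class DiscrepancyKind(str, Enum):
    VALUE_MISMATCH = "value mismatch"
    MISSING_IN_TEXT = "missing in text"
    MISSING_IN_JSON = "missing in JSON"


@dataclass(frozen=True)
class Discrepancy:
    """One itemized difference, addressed by a hierarchical path.

    Paths look like ``STUDY/STUDY_TITLE``, ``SUBJECT_SAMPLE_FACTORS/row[2]/sample``
    or ``MS_METABOLITE_DATA/alanine/S3``.
    """

    path: str
    kind: DiscrepancyKind
    text_value: str | None = None
    json_value: str | None = None

    def __str__(self) -> str:
        return (
            f"{self.path}: {self.kind.value} "
            f"(text={self.text_value!r}, json={self.json_value!r})"
        )


@dataclass
class ComparisonResult:
    status: ComparisonStatus
    discrepancies: list[Discrepancy] = field(default_factory=list)
    reason: str | None = None


def compare(
    text_parse: MWTabFile | ParseFailure | None,
    json_parse: MWTabFile | ParseFailure | None,
) -> ComparisonResult:
    """Compare the per-format parse outcomes of a single analysis.

    ``None`` means the file was absent.  Covers header fields, every
    key-value item, factor rows, sample names and every matrix cell; the
    discrepancy list is ordered by path.
    """
    blockers = []
    for fmt, outcome in (("text", text_parse), ("JSON", json_parse)):
        if outcome is None:
            blockers.append(f"{fmt} file is missing")
        elif isinstance(outcome, ParseFailure):
            blockers.append(f"{fmt} file is unparsable")
    if blockers:
        return ComparisonResult(
            ComparisonStatus.NOT_CHECKED, reason="; ".join(blockers)
        )

    discrepancies: list[Discrepancy] = []
    _compare_headers(text_parse, json_parse, discrepancies)

    text_sections = {s.name: s for s in text_parse.sections}
    json_sections = {s.name: s for s in json_parse.sections}
    # one discrepancy per section present on only one side, not one per key
    for name in sorted(text_sections.keys() | json_sections.keys()):
        ts, js = text_sections.get(name), json_sections.get(name)
        if ts is None:
            discrepancies.append(
                Discrepancy(name, DiscrepancyKind.MISSING_IN_TEXT, json_value="<section>")
            )
            continue
        if js is None:
            discrepancies.append(
                Discrepancy(name, DiscrepancyKind.MISSING_IN_JSON, text_value="<section>")
            )
            continue
        if ts.kind is SectionKind.FACTOR_LIST:
            _compare_factor_rows(name, ts, js, discrepancies)
        elif ts.kind is SectionKind.DATA_MATRIX:
            _compare_matrices(name, ts, js, discrepancies)
        else:
            _compare_items(name, ts, js, discrepancies)

    discrepancies.sort(key=lambda d: d.path)
    status = (
        ComparisonStatus.INCONSISTENT if discrepancies else ComparisonStatus.CONSISTENT
    )
    return ComparisonResult(status, discrepancies)


def _clean(value: str) -> str:
    return value.strip()


def _value_pair(path: str, tv: str | None, jv: str | None, out: list[Discrepancy]) -> None:
    """Emit the discrepancy for one addressed value slot, if any.

    Empty string and absent are distinct: absence is MISSING_IN_*, an
    empty-vs-nonempty difference is a VALUE_MISMATCH.
    """
    if tv is None and jv is None:
        return
    if tv is None:
        out.append(Discrepancy(path, DiscrepancyKind.MISSING_IN_TEXT, json_value=jv))
    elif jv is None:
        out.append(Discrepancy(path, DiscrepancyKind.MISSING_IN_JSON, text_value=tv))
    elif _clean(tv) != _clean(jv):
        out.append(
            Discrepancy(
                path, DiscrepancyKind.VALUE_MISMATCH, text_value=tv, json_value=jv
            )
        )


def _compare_headers(t: MWTabFile, j: MWTabFile, out: list[Discrepancy]) -> None:
    for label, tv, jv in (
        ("STUDY_ID", t.study_id, j.study_id),
        ("ANALYSIS_ID", t.analysis_id, j.analysis_id),
        ("VERSION", t.spec_version, j.spec_version),
        ("CREATED_ON", t.created_on, j.created_on),
    ):
        _value_pair(f"HEADER/{label}", tv, jv, out)


def _compare_items(name, ts, js, out: list[Discrepancy]) -> None:
    t_items, j_items = dict(ts.items), dict(js.items)
    for key in sorted(t_items.keys() | j_items.keys()):
        _value_pair(f"{name}/{key}", t_items.get(key), j_items.get(key), out)


def _compare_factor_rows(name, ts, js, out: list[Discrepancy]) -> None:
    n = max(len(ts.factor_rows), len(js.factor_rows))
    fields = ("subject", "sample", "factors", "additional")
    for i in range(n):
        tr = ts.factor_rows[i] if i < len(ts.factor_rows) else None
        jr = js.factor_rows[i] if i < len(js.factor_rows) else None
        if tr is None:
            out.append(
                Discrepancy(
                    f"{name}/row[{i}]", DiscrepancyKind.MISSING_IN_TEXT, json_value="<row>"
                )
            )
            continue
        if jr is None:
            out.append(
                Discrepancy(
                    f"{name}/row[{i}]", DiscrepancyKind.MISSING_IN_JSON, text_value="<row>"
                )
            )
            continue
        for attr in fields:
            _value_pair(
                f"{name}/row[{i}]/{attr}", getattr(tr, attr), getattr(jr, attr), out
            )


def _compare_matrices(name, ts, js, out: list[Discrepancy]) -> None:
    tm, jm = ts.matrix, js.matrix
    if tm is None or jm is None:
        _value_pair(
            f"{name}/<matrix>",
            None if tm is None else "<matrix>",
            None if jm is None else "<matrix>",
            out,
        )
        return
    n_samples = max(len(tm.sample_names), len(jm.sample_names))
    for i in range(n_samples):
        _value_pair(
            f"{name}/Samples[{i}]",
            tm.sample_names[i] if i < len(tm.sample_names) else None,
            jm.sample_names[i] if i < len(jm.sample_names) else None,
            out,
        )
    t_factors = tm.factor_labels or []
    j_factors = jm.factor_labels or []
    for i in range(max(len(t_factors), len(j_factors))):
        _value_pair(
            f"{name}/Factors[{i}]",
            t_factors[i] if i < len(t_factors) else None,
            j_factors[i] if i < len(j_factors) else None,
            out,
        )
    t_rows, j_rows = dict(tm.rows), dict(jm.rows)
    for feature in sorted(t_rows.keys() | j_rows.keys()):
        tv, jv = t_rows.get(feature), j_rows.get(feature)
        if tv is None:
            out.append(
                Discrepancy(
                    f"{name}/{feature}", DiscrepancyKind.MISSING_IN_TEXT, json_value="<row>"
                )
            )
            continue
        if jv is None:
            out.append(
                Discrepancy(
                    f"{name}/{feature}", DiscrepancyKind.MISSING_IN_JSON, text_value="<row>"
                )
            )
            continue
        for i in range(max(len(tv), len(jv))):
            sample = (
                tm.sample_names[i]
                if i < len(tm.sample_names)
                else (jm.sample_names[i] if i < len(jm.sample_names) else f"[{i}]")
            )
            _value_pair(
                f"{name}/{feature}/{sample}",
                tv[i] if i < len(tv) else None,
                jv[i] if i < len(jv) else None,
                out,
            )
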