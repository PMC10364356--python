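"""Readers and writers for the two mwTab serializations.

The plain-text dialect is the sectioned, tab-delimited deposition format:

    #METABOLOMICS WORKBENCH<TAB>STUDY_ID:ST000001<TAB>ANALYSIS_ID:AN000001<TAB>VERSION:1.5<TAB>CREATED_ON:2023-06-25
    #PROJECT
    PR:PROJECT_TITLE<TAB>...
    ...
    #SUBJECT_SAMPLE_FACTORS
    SUBJECT_SAMPLE_FACTORS<TAB>subject<TAB>sample<TAB>factors<TAB>additional
    ...
    #MS_METABOLITE_DATA
    MS_METABOLITE_DATA_START
    Samples<TAB>S1<TAB>S2
    Factors<TAB>f1<TAB>f2
    alanine<TAB>1.2<TAB>3.4
    MS_METABOLITE_DATA_END
    #END

The JSON mirror is one top-level object whose first key carries the header
fields and whose remaining keys are the sections in order.

Both parsers are *total*: malformed content yields a :class:`ParseFailure`
(category GROSS_FORMATTING), never an exception.  Only genuine I/O errors on
a stream propagate.  The gross/minor boundary: anything that prevents
tokenizing the header, a section header, an item line or a block sentinel is
gross; everything detectable on a successfully built file is left to the
schema validator.
"""

from __future__ import annotations

import io
import json
from typing import IO, Union

from .model import (
    DataMatrix,
    FactorRow,
    MWTabFile,
    ParseFailure,
    Section,
    SectionKind,
    SECTION_PREFIXES,
    SourceFormat,
    section_kind,
)

# --- grammar table for the text dialect (a dialect fix is a data change) ----
HEADER_SENTINEL = "#METABOLOMICS WORKBENCH"
END_SENTINEL = "#END"
HEADER_TOKENS = ("STUDY_ID", "ANALYSIS_ID", "VERSION", "CREATED_ON")
REQUIRED_HEADER_TOKENS = ("STUDY_ID", "ANALYSIS_ID")
SAMPLES_ROW_LABEL = "Samples"
FACTORS_ROW_LABEL = "Factors"
FACTOR_ROW_LABEL = "SUBJECT_SAMPLE_FACTORS"

# JSON mirror key names
JSON_HEADER_KEY = "METABOLOMICS WORKBENCH"
JSON_FACTOR_KEYS = ("Subject ID", "Sample ID", "Factors", "Additional sample data")
JSON_SAMPLES_KEY = "Samples"
JSON_FACTORS_KEY = "Factors"
JSON_DATA_KEY = "Data"
JSON_FEATURE_KEY = "Feature"
JSON_VALUES_KEY = "Values"

Content = Union[str, bytes, IO]


def _read_text(content: Content) -> str:
    """Decode input to text; raises UnicodeDecodeError on bad bytes."""
    if hasattr(content, "read"):
        content = content.read()
    if isinstance(content, bytes):
        content = content.decode("utf-8")
    # tolerate a BOM and CRLF line endings from real deposition files
    return content.lstrip("﻿").replace("\r\n", "\n")


def _parse_header_line(line: str) -> dict[str, str]:
    parts = line.split("\t")
    if parts[0] != HEADER_SENTINEL:
        raise _Gross(f"first line is not {HEADER_SENTINEL!r}", "line 1")
    fields = {t: "" for t in HEADER_TOKENS}
    for token in parts[1:]:
        if ":" not in token:
            raise _Gross(f"untokenizable header field {token!r}", "line 1")
        key, value = token.split(":", 1)
        fields[key] = value
    for token in REQUIRED_HEADER_TOKENS:
        if not fields[token]:
            raise _Gross(f"header lacks {token}", "line 1")
    return fields


class _Gross(Exception):
    def __init__(self, message: str, location: str | None = None):
        super().__init__(message)
        self.message = message
        self.location = location


def parse_mwtab_text(content: Content) -> MWTabFile | ParseFailure:
    """Parse the plain-text dialect into an MWTabFile, or a ParseFailure."""
    try:
        text = _read_text(content)
    except UnicodeDecodeError as exc:
        return ParseFailure(SourceFormat.TEXT, f"unreadable encoding: {exc}")
    try:
        return _parse_text(text)
    except _Gross as exc:
        return ParseFailure(SourceFormat.TEXT, exc.message, exc.location)


def _parse_text(text: str) -> MWTabFile:
    lines = text.split("\n")
    # drop trailing blank lines only; internal blanks are suspicious but kept
    while lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise _Gross("blank file: no content to parse")

    header = _parse_header_line(lines[0])
    mwfile = MWTabFile(
        study_id=header["STUDY_ID"],
        analysis_id=header["ANALYSIS_ID"],
        spec_version=header["VERSION"],
        created_on=header["CREATED_ON"],
        source_format=SourceFormat.TEXT,
    )

    i = 1
    current: Section | None = None
    saw_end = False
    while i < len(lines):
        line = lines[i]
        lineno = i + 1
        if line == END_SENTINEL:
            saw_end = True
            i += 1
            continue
        if saw_end and line:
            raise _Gross("content after end sentinel", f"line {lineno}")
        if line == "":
            i += 1  # stray blank line between sections: tolerated
            continue
        if line.startswith("#"):
            name = line[1:]
            if not name:
                raise _Gross("empty section header", f"line {lineno}")
            current = Section(name=name, kind=section_kind(name))
            if current.kind is SectionKind.DATA_MATRIX:
                i = _parse_matrix_block(lines, i + 1, current)
                mwfile.sections.append(current)
                current = None
                continue
            mwfile.sections.append(current)
            i += 1
            continue
        if current is None:
            raise _Gross(f"item line outside any section: {line!r}", f"line {lineno}")
        if current.kind is SectionKind.FACTOR_LIST:
            parts = line.split("\t")
            if parts[0] != FACTOR_ROW_LABEL or len(parts) != 5:
                raise _Gross(
                    f"untokenizable factor row in {current.name}", f"line {lineno}"
                )
            current.factor_rows.append(FactorRow(*parts[1:5]))
        else:
            if "\t" not in line:
                raise _Gross(
                    f"item line without tab in {current.name}: {line!r}",
                    f"line {lineno}",
                )
            key_part, value = line.split("\t", 1)
            if ":" not in key_part:
                raise _Gross(
                    f"item key without prefix in {current.name}: {key_part!r}",
                    f"line {lineno}",
                )
            _prefix, key = key_part.split(":", 1)
            if key in current.keys():
                # duplicate keys: keep the first, surface as a minor issue
                mwfile.parse_notes.append(
                    f"duplicate key {key} in section {current.name}; first kept"
                )
            else:
                current.items.append((key, value))
        i += 1
    return mwfile


def _parse_matrix_block(lines: list[str], start: int, section: Section) -> int:
    """Parse <NAME>_START .. <NAME>_END; returns index past the end sentinel."""
    start_sentinel = f"{section.name}_START"
    end_sentinel = f"{section.name}_END"
    if start >= len(lines) or lines[start] != start_sentinel:
        raise _Gross(
            f"expected {start_sentinel} after #{section.name}", f"line {start + 1}"
        )
    matrix = DataMatrix()
    i = start + 1
    terminated = False
    while i < len(lines):
        line = lines[i]
        if line == end_sentinel:
            terminated = True
            i += 1
            break
        if line.startswith("#") or line.endswith("_START"):
            break  # ran into the next section: the block was never closed
        parts = line.split("\t")
        if parts[0] == SAMPLES_ROW_LABEL and not matrix.sample_names and not matrix.rows:
            matrix.sample_names = parts[1:]
        elif parts[0] == FACTORS_ROW_LABEL and matrix.factor_labels is None and not matrix.rows:
            matrix.factor_labels = parts[1:]
        else:
            values = parts[1:]
            if len(values) != len(matrix.sample_names):
                raise _Gross(
                    f"row {parts[0]!r} has {len(values)} values for "
                    f"{len(matrix.sample_names)} samples in {section.name}",
                    f"line {i + 1}",
                )
            matrix.rows.append((parts[0], values))
        i += 1
    if not terminated:
        raise _Gross(
            f"unterminated {section.name} block: missing {end_sentinel}",
            f"line {start + 1}",
        )
    section.matrix = matrix
    return i


def write_mwtab_text(mwfile: MWTabFile) -> str:
    """Serialize to the canonical text dialect (inverse of parse_mwtab_text)."""
    out = io.StringIO()
    header_fields = {
        "STUDY_ID": mwfile.study_id,
        "ANALYSIS_ID": mwfile.analysis_id,
        "VERSION": mwfile.spec_version,
        "CREATED_ON": mwfile.created_on,
    }
    tokens = "\t".join(f"{k}:{header_fields[k]}" for k in HEADER_TOKENS)
    out.write(f"{HEADER_SENTINEL}\t{tokens}\n")
    for section in mwfile.sections:
        out.write(f"#{section.name}\n")
        if section.kind is SectionKind.FACTOR_LIST:
            for row in section.factor_rows:
                out.write(
                    f"{FACTOR_ROW_LABEL}\t{row.subject}\t{row.sample}"
                    f"\t{row.factors}\t{row.additional}\n"
                )
        elif section.kind is SectionKind.DATA_MATRIX:
            matrix = section.matrix or DataMatrix()
            out.write(f"{section.name}_START\n")
            out.write("\t".join([SAMPLES_ROW_LABEL, *matrix.sample_names]) + "\n")
            if matrix.factor_labels is not None:
                out.write("\t".join([FACTORS_ROW_LABEL, *matrix.factor_labels]) + "\n")
            for name, values in matrix.rows:
                out.write("\t".join([name, *values]) + "\n")
            out.write(f"{section.name}_END\n")
        else:
            prefix = SECTION_PREFIXES.get(section.name, section.name[:2].upper())
            for key, value in section.items:
                out.write(f"{prefix}:{key}\t{value}\n")
    out.write(f"{END_SENTINEL}\n")
    return out.getvalue()


def parse_mwtab_json(content: Content) -> MWTabFile | ParseFailure:
    """Parse the JSON mirror into an MWTabFile, or a ParseFailure."""
    try:
        text = _read_text(content)
    except UnicodeDecodeError as exc:
        return ParseFailure(SourceFormat.JSON, f"unreadable encoding: {exc}")
    if not text.strip():
        return ParseFailure(SourceFormat.JSON, "blank file: no content to parse")
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        return ParseFailure(
            SourceFormat.JSON,
            f"invalid JSON syntax: {exc.msg}",
            f"line {exc.lineno} column {exc.colno}",
        )
    try:
        return _from_json_obj(obj)
    except _Gross as exc:
        return ParseFailure(SourceFormat.JSON, exc.message, exc.location)


def _from_json_obj(obj) -> MWTabFile:
    if not isinstance(obj, dict):
        raise _Gross(f"top level must be an object, got {type(obj).__name__}", "$")
    header = obj.get(JSON_HEADER_KEY)
    if not isinstance(header, dict):
        raise _Gross(f"missing {JSON_HEADER_KEY!r} header object", "$")
    for token in REQUIRED_HEADER_TOKENS:
        if not header.get(token):
            raise _Gross(f"header lacks {token}", f"$.{JSON_HEADER_KEY}")
    mwfile = MWTabFile(
        study_id=str(header["STUDY_ID"]),
        analysis_id=str(header["ANALYSIS_ID"]),
        spec_version=str(header.get("VERSION", "")),
        created_on=str(header.get("CREATED_ON", "")),
        source_format=SourceFormat.JSON,
    )
    for name, body in obj.items():
        if name == JSON_HEADER_KEY:
            continue
        section = Section(name=name, kind=section_kind(name))
        path = f"$.{name}"
        if section.kind is SectionKind.FACTOR_LIST:
            if not isinstance(body, list):
                raise _Gross(f"{name} must be an array", path)
            for idx, row in enumerate(body):
                if not isinstance(row, dict):
                    raise _Gross(f"{name}[{idx}] must be an object", path)
                section.factor_rows.append(
                    FactorRow(*(str(row.get(k, "")) for k in JSON_FACTOR_KEYS))
                )
        elif section.kind is SectionKind.DATA_MATRIX:
            if not isinstance(body, dict):
                raise _Gross(f"{name} must be an object", path)
            samples = body.get(JSON_SAMPLES_KEY, [])
            data = body.get(JSON_DATA_KEY, [])
            if not isinstance(samples, list) or not isinstance(data, list):
                raise _Gross(f"{name} matrix shape is malformed", path)
            factors = body.get(JSON_FACTORS_KEY)
            matrix = DataMatrix(
                sample_names=[str(s) for s in samples],
                factor_labels=None if factors is None else [str(x) for x in factors],
            )
            for idx, row in enumerate(data):
                if not isinstance(row, dict) or JSON_FEATURE_KEY not in row:
                    raise _Gross(f"{name}.Data[{idx}] is malformed", path)
                values = [str(v) for v in row.get(JSON_VALUES_KEY, [])]
                if len(values) != len(matrix.sample_names):
                    raise _Gross(
                        f"{name}.Data[{idx}] has {len(values)} values for "
                        f"{len(matrix.sample_names)} samples",
                        path,
                    )
                matrix.rows.append((str(row[JSON_FEATURE_KEY]), values))
            section.matrix = matrix
        else:
            if not isinstance(body, dict):
                raise _Gross(f"{name} must be an object", path)
            section.items = [(str(k), str(v)) for k, v in body.items()]
        mwfile.sections.append(section)
    return mwfile


def write_mwtab_json(mwfile: MWTabFile) -> str:
    """Serialize to the JSON mirror with stable key ordering."""
    obj: dict = {
        JSON_HEADER_KEY: {
            "STUDY_ID": mwfile.study_id,
            "ANALYSIS_ID": mwfile.analysis_id,
            "VERSION": mwfile.spec_version,
            "CREATED_ON": mwfile.created_on,
        }
    }
    for section in mwfile.sections:
        if section.kind is SectionKind.FACTOR_LIST:
            obj[section.name] = [
                dict(zip(JSON_FACTOR_KEYS, row.as_tuple()))
                for row in section.factor_rows
            ]
        elif section.kind is SectionKind.DATA_MATRIX:
            matrix = section.matrix or DataMatrix()
            body: dict = {JSON_SAMPLES_KEY: list(matrix.sample_names)}
            if matrix.factor_labels is not None:
                body[JSON_FACTORS_KEY] = list(matrix.factor_labels)
            body[JSON_DATA_KEY] = [
                {JSON_FEATURE_KEY: name, JSON_VALUES_KEY: list(values)}
                for name, values in matrix.rows
            ]
            obj[section.name] = body
        else:
            obj[section.name] = dict(section.items)
    return json.dumps(obj, indent=2, ensure_ascii=False) + "\n"
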