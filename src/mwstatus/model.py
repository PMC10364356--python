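"""Core in-memory model for Metabolomics Workbench analysis files.

A single :class:`MWTabFile` represents one analysis regardless of whether it
was read from the sectioned plain-text dialect or its JSON mirror.  The model
is deliberately lossless and string-typed: values are never numerically
coerced at the I/O layer, and section/row order is preserved exactly as read
so the text form can be re-serialized byte-identically.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field


STUDY_ID_PATTERN = re.compile(r"^ST[0-9]{6}$")
ANALYSIS_ID_PATTERN = re.compile(r"^AN[0-9]{6}$")


class SourceFormat(str, enum.Enum):
    """Which serialization an MWTabFile was read from."""

    TEXT = "txt"
    JSON = "json"


class SectionKind(str, enum.Enum):
    KEY_VALUE = "key_value"
    FACTOR_LIST = "factor_list"
    DATA_MATRIX = "data_matrix"


class FileStatus(str, enum.Enum):
    """Four-way per-(analysis, format) status taxonomy.

    PASSING        — parsed and no schema issues.
    PARSING_ERROR  — gross formatting error prevented parsing (blank files
                     included).
    VALIDATION_ERROR — parsed, but inconsistent with the file-format
                     specification (minor formatting errors).
    MISSING        — the file could not be retrieved at all.
    """

    PASSING = "Passing"
    PARSING_ERROR = "Parsing error"
    VALIDATION_ERROR = "Validation error"
    MISSING = "Missing"


class ComparisonStatus(str, enum.Enum):
    CONSISTENT = "Consistent"
    INCONSISTENT = "Inconsistent"
    NOT_CHECKED = "Not checked"


class FetchOutcome(str, enum.Enum):
    """Whether a file could be retrieved at all (zero bytes still counts)."""

    RETRIEVED = "retrieved"
    ABSENT = "absent"


# Section-name vocabulary.  Kind is determined by name; unknown names are
# preserved by the parser and flagged downstream by the validator.
FACTOR_LIST_SECTIONS = ("SUBJECT_SAMPLE_FACTORS",)
DATA_MATRIX_SECTIONS = (
    "MS_METABOLITE_DATA",
    "NMR_METABOLITE_DATA",
    "NMR_BINNED_DATA",
    "METABOLITES",
)
KEY_VALUE_SECTIONS = (
    "PROJECT",
    "STUDY",
    "SUBJECT",
    "COLLECTION",
    "TREATMENT",
    "SAMPLEPREP",
    "CHROMATOGRAPHY",
    "ANALYSIS",
    "MS",
    "NMR",
)
KNOWN_SECTIONS = KEY_VALUE_SECTIONS + FACTOR_LIST_SECTIONS + DATA_MATRIX_SECTIONS

# Two-letter item-line prefixes of the text dialect, one per key-value section.
SECTION_PREFIXES = {
    "PROJECT": "PR",
    "STUDY": "ST",
    "SUBJECT": "SU",
    "COLLECTION": "CO",
    "TREATMENT": "TR",
    "SAMPLEPREP": "SP",
    "CHROMATOGRAPHY": "CH",
    "ANALYSIS": "AN",
    "MS": "MS",
    "NMR": "NM",
}


def section_kind(name: str) -> SectionKind:
    """Kind of a section, determined purely by its name."""
    if name in FACTOR_LIST_SECTIONS:
        return SectionKind.FACTOR_LIST
    if name in DATA_MATRIX_SECTIONS:
        return SectionKind.DATA_MATRIX
    return SectionKind.KEY_VALUE


@dataclass
class FactorRow:
    """One SUBJECT_SAMPLE_FACTORS row: a per-sample factor assignment."""

    subject: str
    sample: str
    factors: str
    additional: str

    def as_tuple(self) -> tuple[str, str, str, str]:
        return (self.subject, self.sample, self.factors, self.additional)


@dataclass
class DataMatrix:
    """Feature-by-sample block of string values.

    ``rows`` maps feature name -> ordered values, one per sample.  An empty
    matrix (no samples, no rows) is representable: analyses that lack the
    actual experimental data do occur in the wild.
    """

    sample_names: list[str] = field(default_factory=list)
    factor_labels: list[str] | None = None
    rows: list[tuple[str, list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, values in self.rows:
            if len(values) != len(self.sample_names):
                raise ValueError(
                    f"row {name!r} has {len(values)} values for "
                    f"{len(self.sample_names)} samples"
                )


@dataclass
class Section:
    """One named section of an analysis file.

    Exactly one of ``items`` / ``factor_rows`` / ``matrix`` is meaningful,
    selected by ``kind`` (which is itself a pure function of ``name``).
    """

    name: str
    kind: SectionKind
    items: list[tuple[str, str]] = field(default_factory=list)
    factor_rows: list[FactorRow] = field(default_factory=list)
    matrix: DataMatrix | None = None

    def get(self, key: str) -> str | None:
        for k, v in self.items:
            if k == key:
                return v
        return None

    def keys(self) -> list[str]:
        return [k for k, _ in self.items]


@dataclass
class MWTabFile:
    """Canonical in-memory representation of one analysis data file."""

    study_id: str
    analysis_id: str
    spec_version: str
    created_on: str
    sections: list[Section] = field(default_factory=list)
    source_format: SourceFormat | None = None
    # Parser-recorded notes about tolerated oddities (e.g. duplicate keys),
    # surfaced by the validator as minor issues.
    parse_notes: list[str] = field(default_factory=list)

    def section(self, name: str) -> Section | None:
        for s in self.sections:
            if s.name == name:
                return s
        return None

    def section_names(self) -> list[str]:
        return [s.name for s in self.sections]

    @property
    def analysis_type(self) -> str | None:
        """"MS" or "NMR" per the ANALYSIS section, if declared."""
        analysis = self.section("ANALYSIS")
        if analysis is None:
            return None
        return analysis.get("ANALYSIS_TYPE")

    def structurally_equal(self, other: "MWTabFile") -> bool:
        """Equality ignoring source format and parse notes."""
        return _strip(self) == _strip(other)


def _strip(f: MWTabFile) -> tuple:
    return (
        f.study_id,
        f.analysis_id,
        f.spec_version,
        f.created_on,
        [
            (
                s.name,
                s.kind,
                list(s.items),
                [r.as_tuple() for r in s.factor_rows],
                (
                    None
                    if s.matrix is None
                    else (
                        list(s.matrix.sample_names),
                        None
                        if s.matrix.factor_labels is None
                        else list(s.matrix.factor_labels),
                        [(n, list(v)) for n, v in s.matrix.rows],
                    )
                ),
            )
            for s in f.sections
        ],
    )


@dataclass
class ParseFailure:
    """A gross formatting error: the file could not be parsed at all.

    Carries enough context to render a validation log even for blank files.
    """

    format: SourceFormat
    message: str
    location: str | None = None
    category: str = "GROSS_FORMATTING"
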