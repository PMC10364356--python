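"""Versioned schema validation and the four-way file-status taxonomy.

The schema is pure data (YAML rule tables shipped under ``mwstatus/schemas``):
which sections are required, which keys each section must carry, and which
extra sections a mass-spectrometry versus NMR analysis needs.  Adding a new
specification version means adding a table, not code.

Status precedence for one (analysis, format):

    file absent            -> MISSING
    gross formatting error -> PARSING_ERROR
    any schema issue       -> VALIDATION_ERROR
    otherwise              -> PASSING
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .model import (
    FetchOutcome,
    FileStatus,
    KNOWN_SECTIONS,
    MWTabFile,
    ParseFailure,
    SectionKind,
)

#: token in analysis_type_rules standing for "any metabolite-data matrix block"
DATA_BLOCK_TOKEN = "data_block"

DEFAULT_VERSION = "1.5"
SHIPPED_VERSIONS = ("1.5", "1.6")


@dataclass(frozen=True)
class ValidationIssue:
    """One minor formatting error found on a successfully parsed file."""

    section: str
    key: str | None
    message: str
    severity: str = "SCHEMA"

    def __str__(self) -> str:
        loc = self.section if self.key is None else f"{self.section}:{self.key}"
        return f"{self.severity} {loc} - {self.message}"


@dataclass
class SectionRule:
    required_keys: list[str] = field(default_factory=list)
    key_patterns: dict[str, str] = field(default_factory=dict)


@dataclass
class SchemaSpec:
    """One version of the file-format specification, loaded from a rule table."""

    version: str
    required_sections: list[str]
    analysis_type_rules: dict[str, list[str]]
    section_rules: dict[str, SectionRule]
    min_factor_rows: int = 1

    @classmethod
    def from_mapping(cls, data: dict) -> "SchemaSpec":
        return cls(
            version=str(data["version"]),
            required_sections=list(data.get("required_sections", [])),
            analysis_type_rules={
                k: list(v) for k, v in data.get("analysis_type_rules", {}).items()
            },
            section_rules={
                name: SectionRule(
                    required_keys=list((rule or {}).get("required_keys", [])),
                    key_patterns=dict((rule or {}).get("key_patterns", {})),
                )
                for name, rule in data.get("section_rules", {}).items()
            },
            min_factor_rows=int(data.get("min_factor_rows", 1)),
        )


def load_schema(version: str) -> SchemaSpec:
    """Load a shipped schema rule table by version string."""
    if version not in SHIPPED_VERSIONS:
        raise KeyError(f"no shipped schema for version {version!r}")
    ref = resources.files("mwstatus.schemas").joinpath(f"v{version}.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return SchemaSpec.from_mapping(yaml.safe_load(fh))


def load_registry() -> dict[str, SchemaSpec]:
    return {v: load_schema(v) for v in SHIPPED_VERSIONS}


@dataclass
class SchemaSelection:
    """Which schema version was applied and why (for the validation log)."""

    spec: SchemaSpec
    reason: str
    issues: list[ValidationIssue] = field(default_factory=list)


def select_schema(
    mwfile: MWTabFile,
    registry: dict[str, SchemaSpec],
    default_version: str = DEFAULT_VERSION,
) -> SchemaSelection:
    """Pick the schema matching the file's header VERSION, else the default.

    Legacy files predate versioning, so an absent or unregistered version
    falls back to the default; an absent version additionally surfaces as a
    schema issue so curators can see the header is incomplete.
    """
    if default_version not in registry:
        raise KeyError(f"default version {default_version!r} not in registry")
    declared = mwfile.spec_version.strip()
    if not declared:
        return SchemaSelection(
            spec=registry[default_version],
            reason=f"header VERSION absent; defaulted to {default_version}",
            issues=[
                ValidationIssue(
                    section="HEADER",
                    key="VERSION",
                    message="header lacks a file-format VERSION field",
                )
            ],
        )
    if declared in registry:
        return SchemaSelection(
            spec=registry[declared],
            reason=f"header VERSION {declared} matched a registered schema",
        )
    return SchemaSelection(
        spec=registry[default_version],
        reason=(
            f"header VERSION {declared!r} not registered; "
            f"defaulted to {default_version}"
        ),
    )


def validate_file(mwfile: MWTabFile, schema: SchemaSpec) -> list[ValidationIssue]:
    """All schema issues on a parsed file, in deterministic order.

    Order: required-section checks in the rule table's order, then per-section
    key checks, then analysis-type checks, then unknown-section and
    parser-note issues.  The file is never mutated.
    """
    issues: list[ValidationIssue] = []
    present = {s.name for s in mwfile.sections}

    for name in schema.required_sections:
        if name not in present:
            issues.append(
                ValidationIssue(name, None, f"required section {name} is absent")
            )

    for name, rule in schema.section_rules.items():
        section = mwfile.section(name)
        if section is None:
            continue
        section_keys = set(section.keys())
        for key in rule.required_keys:
            if key not in section_keys:
                issues.append(
                    ValidationIssue(name, key, f"required key {key} is absent")
                )
        for key, pattern in rule.key_patterns.items():
            value = section.get(key)
            if value is not None and not re.fullmatch(pattern, value):
                issues.append(
                    ValidationIssue(
                        name, key, f"value {value!r} does not match {pattern!r}"
                    )
                )

    factors = mwfile.section("SUBJECT_SAMPLE_FACTORS")
    if factors is not None and len(factors.factor_rows) < schema.min_factor_rows:
        issues.append(
            ValidationIssue(
                "SUBJECT_SAMPLE_FACTORS",
                None,
                f"fewer than {schema.min_factor_rows} factor row(s)",
            )
        )

    analysis_type = mwfile.analysis_type
    if analysis_type in schema.analysis_type_rules:
        has_data_block = any(
            s.kind is SectionKind.DATA_MATRIX and s.name != "METABOLITES"
            for s in mwfile.sections
        )
        for required in schema.analysis_type_rules[analysis_type]:
            if required == DATA_BLOCK_TOKEN:
                if not has_data_block:
                    issues.append(
                        ValidationIssue(
                            "DATA",
                            None,
                            f"{analysis_type} analysis lacks a metabolite-data block",
                        )
                    )
            elif required not in present:
                issues.append(
                    ValidationIssue(
                        required,
                        None,
                        f"section {required} is required for {analysis_type} analyses",
                    )
                )
    elif mwfile.section("ANALYSIS") is not None and analysis_type is not None:
        issues.append(
            ValidationIssue(
                "ANALYSIS",
                "ANALYSIS_TYPE",
                f"unrecognized analysis type {analysis_type!r}",
            )
        )

    for section in mwfile.sections:
        if section.name not in KNOWN_SECTIONS:
            issues.append(
                ValidationIssue(
                    section.name, None, f"unknown section name {section.name}"
                )
            )

    for note in mwfile.parse_notes:
        issues.append(ValidationIssue("PARSER", None, note))

    return issues


def classify_status(
    fetch_outcome: FetchOutcome,
    parse_outcome: MWTabFile | ParseFailure | None,
    issues: list[ValidationIssue] | None,
) -> FileStatus:
    """Collapse (fetched?, parsed?, issues?) into the four-way status."""
    if fetch_outcome is FetchOutcome.ABSENT:
        if parse_outcome is not None or issues is not None:
            raise ValueError("absent file cannot carry a parse outcome or issues")
        return FileStatus.MISSING
    if isinstance(parse_outcome, ParseFailure):
        if issues is not None:
            raise ValueError("unparsable file cannot carry validation issues")
        return FileStatus.PARSING_ERROR
    if not isinstance(parse_outcome, MWTabFile):
        raise ValueError("retrieved file must have a parse outcome")
    if issues is None:
        raise ValueError("parsed file must come with its issue list")
    return FileStatus.VALIDATION_ERROR if issues else FileStatus.PASSING
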