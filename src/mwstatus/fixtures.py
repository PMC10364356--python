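"""Synthetic corpus generator: paired text/JSON analyses with known defects.

The generator emulates the kinds of file problems a live repository mirror
encounters, one defect category per analysis, and writes a ground-truth
manifest recording the status each analysis *must* receive from the
pipeline.  Every status in the file-status taxonomy and every comparison
outcome has at least one generating defect, so the manifest is a complete
oracle for end-to-end tests — no download required.

Content realism is deliberately modest (a small vocabulary of species,
instruments and metabolite names); what matters is schema-shape fidelity:
valid analyses are valid *by construction* under the v1.5 rule table, and
each injected mutation maps to exactly one downstream finding (one deleted
required key -> one validation issue; one drifted value -> one comparison
discrepancy).
"""

from __future__ import annotations

import copy
import json
import random
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .model import (
    ComparisonStatus,
    DataMatrix,
    FactorRow,
    FileStatus,
    MWTabFile,
    Section,
    SectionKind,
)
from .mwtab_io import write_mwtab_json, write_mwtab_text
from .schema_validator import load_schema

MANIFEST_FILENAME = "manifest.json"


class Defect(str, Enum):
    """Defect taxonomy: what is wrong with one analysis's file pair."""

    NONE = "NONE"
    MISSING_TEXT = "MISSING_TEXT"
    MISSING_JSON = "MISSING_JSON"
    MISSING_BOTH = "MISSING_BOTH"
    BLANK_TEXT = "BLANK_TEXT"
    GROSS_TEXT = "GROSS_TEXT"
    GROSS_JSON = "GROSS_JSON"
    SCHEMA_TEXT = "SCHEMA_TEXT"
    SCHEMA_JSON = "SCHEMA_JSON"
    SCHEMA_BOTH = "SCHEMA_BOTH"
    VALUE_DRIFT = "VALUE_DRIFT"


#: defects whose mutation_count matters
_COUNTED = {Defect.SCHEMA_TEXT, Defect.SCHEMA_JSON, Defect.SCHEMA_BOTH, Defect.VALUE_DRIFT}

#: deterministic consequence of each defect:
#: (text status, JSON status, comparison status)
EXPECTED_OUTCOMES: dict[Defect, tuple[FileStatus, FileStatus, ComparisonStatus]] = {
    Defect.NONE: (FileStatus.PASSING, FileStatus.PASSING, ComparisonStatus.CONSISTENT),
    Defect.MISSING_TEXT: (FileStatus.MISSING, FileStatus.PASSING, ComparisonStatus.NOT_CHECKED),
    Defect.MISSING_JSON: (FileStatus.PASSING, FileStatus.MISSING, ComparisonStatus.NOT_CHECKED),
    Defect.MISSING_BOTH: (FileStatus.MISSING, FileStatus.MISSING, ComparisonStatus.NOT_CHECKED),
    Defect.BLANK_TEXT: (FileStatus.PARSING_ERROR, FileStatus.PASSING, ComparisonStatus.NOT_CHECKED),
    Defect.GROSS_TEXT: (FileStatus.PARSING_ERROR, FileStatus.PASSING, ComparisonStatus.NOT_CHECKED),
    Defect.GROSS_JSON: (FileStatus.PASSING, FileStatus.PARSING_ERROR, ComparisonStatus.NOT_CHECKED),
    # deleting required keys from one serialization only makes the pair differ,
    # so the one-sided schema defects are also inconsistent
    Defect.SCHEMA_TEXT: (FileStatus.VALIDATION_ERROR, FileStatus.PASSING, ComparisonStatus.INCONSISTENT),
    Defect.SCHEMA_JSON: (FileStatus.PASSING, FileStatus.VALIDATION_ERROR, ComparisonStatus.INCONSISTENT),
    Defect.SCHEMA_BOTH: (FileStatus.VALIDATION_ERROR, FileStatus.VALIDATION_ERROR, ComparisonStatus.CONSISTENT),
    Defect.VALUE_DRIFT: (FileStatus.PASSING, FileStatus.PASSING, ComparisonStatus.INCONSISTENT),
}


@dataclass(frozen=True)
class DefectSpec:
    defect: Defect
    mutation_count: int = 1

    def __post_init__(self) -> None:
        if self.defect in _COUNTED and self.mutation_count < 1:
            raise ValueError(f"{self.defect.value} needs mutation_count >= 1")


@dataclass
class ManifestEntry:
    study_id: str
    analysis_id: str
    spec: DefectSpec
    expected_text_status: FileStatus
    expected_json_status: FileStatus
    expected_comparison: ComparisonStatus


@dataclass
class DefectManifest:
    """Ground truth for a generated corpus: the oracle for end-to-end tests."""

    seed: int
    entries: dict[str, ManifestEntry] = field(default_factory=dict)

    def inventory(self) -> dict[str, list[str]]:
        mapping: dict[str, list[str]] = {}
        for entry in self.entries.values():
            mapping.setdefault(entry.study_id, []).append(entry.analysis_id)
        return {st: sorted(ans) for st, ans in sorted(mapping.items())}

    def expected_tallies(self):
        """(text status counts, JSON status counts, comparison counts)."""
        text = {s: 0 for s in FileStatus}
        jsn = {s: 0 for s in FileStatus}
        comp = {s: 0 for s in ComparisonStatus}
        for entry in self.entries.values():
            text[entry.expected_text_status] += 1
            jsn[entry.expected_json_status] += 1
            comp[entry.expected_comparison] += 1
        return text, jsn, comp

    def save(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "analyses": {
                aid: {
                    "study_id": e.study_id,
                    "defect": e.spec.defect.value,
                    "mutation_count": e.spec.mutation_count,
                    "expected_text_status": e.expected_text_status.value,
                    "expected_json_status": e.expected_json_status.value,
                    "expected_comparison": e.expected_comparison.value,
                }
                for aid, e in sorted(self.entries.items())
            },
        }
        Path(path).write_text(
            json.dumps(data, indent=2) + "\n", encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "DefectManifest":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        manifest = cls(seed=data.get("seed", 0))
        for aid, e in data["analyses"].items():
            manifest.entries[aid] = ManifestEntry(
                study_id=e["study_id"],
                analysis_id=aid,
                spec=DefectSpec(Defect(e["defect"]), e.get("mutation_count", 1)),
                expected_text_status=FileStatus(e["expected_text_status"]),
                expected_json_status=FileStatus(e["expected_json_status"]),
                expected_comparison=ComparisonStatus(e["expected_comparison"]),
            )
        return manifest


# --------------------------------------------------------------------------
# plausible-content vocabulary (realism is not a goal; schema shape is)

_FIRST_NAMES = ["Ada", "Grace", "Linus", "Rosalind", "Barbara", "Kary", "Dorothy"]
_LAST_NAMES = ["Hopper", "Franklin", "McClintock", "Mullis", "Crowfoot", "Carver"]
_INSTITUTES = [
    "University of Example",
    "Institute for Metabolic Research",
    "Central Plains Medical Center",
    "Coastal Marine Laboratory",
]
_SPECIES = ["Homo sapiens", "Mus musculus", "Rattus norvegicus", "Arabidopsis thaliana"]
_SUBJECT_TYPES = ["Human", "Mammal", "Plant"]
_MS_INSTRUMENTS = ["Agilent 6550 QTOF", "Thermo Q Exactive", "Sciex TripleTOF 6600"]
_NMR_INSTRUMENTS = ["Bruker Avance III 600", "Varian INOVA 500"]
_COLUMNS = ["Waters Acquity BEH C18", "Agilent Zorbax Eclipse XDB-C18", "HILICON iHILIC"]
_METABOLITES = [
    "alanine", "glycine", "serine", "valine", "leucine", "isoleucine",
    "proline", "threonine", "cysteine", "methionine", "glutamate", "glutamine",
    "asparagine", "aspartate", "lysine", "arginine", "histidine", "tyrosine",
    "tryptophan", "phenylalanine", "citrate", "succinate", "fumarate", "malate",
    "lactate", "pyruvate", "glucose", "fructose", "sucrose", "ribose",
    "inosine", "adenosine", "uridine", "creatinine", "taurine", "carnitine",
]
_FACTORS = ["Control", "Treatment", "Disease", "Vehicle"]


def _kv(name: str, items: list[tuple[str, str]]) -> Section:
    return Section(name=name, kind=SectionKind.KEY_VALUE, items=items)


def generate_valid_analysis(
    seed: int,
    study_id: str,
    analysis_id: str,
    analysis_type: str = "MS",
    n_samples: int = 6,
    n_metabolites: int = 12,
) -> MWTabFile:
    """A v1.5-valid analysis, fully determined by the seed.

    All required sections are populated with plausible strings and the data
    block holds an ``n_metabolites x n_samples`` matrix of numeric strings.
    """
    if n_samples < 1 or n_metabolites < 1:
        raise ValueError("counts must be >= 1")
    if analysis_type not in ("MS", "NMR"):
        raise ValueError(f"unknown analysis type {analysis_type!r}")
    rng = random.Random(seed)
    first, last = rng.choice(_FIRST_NAMES), rng.choice(_LAST_NAMES)
    institute = rng.choice(_INSTITUTES)
    species = rng.choice(_SPECIES)
    email = f"{first.lower()}.{last.lower()}@example.org"
    created = f"20{rng.randint(18, 23)}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"

    mwfile = MWTabFile(
        study_id=study_id,
        analysis_id=analysis_id,
        spec_version="1.5",
        created_on=created,
    )
    mwfile.sections.append(
        _kv(
            "PROJECT",
            [
                ("PROJECT_TITLE", f"Metabolic profiling of {species}"),
                ("PROJECT_SUMMARY", "Untargeted profiling of polar metabolites"),
                ("FIRST_NAME", first),
                ("LAST_NAME", last),
                ("INSTITUTE", institute),
                ("EMAIL", email),
            ],
        )
    )
    mwfile.sections.append(
        _kv(
            "STUDY",
            [
                ("STUDY_TITLE", f"{analysis_type} study of {species} ({study_id})"),
                ("STUDY_SUMMARY", "Comparison of treatment and control groups"),
                ("INSTITUTE", institute),
                ("FIRST_NAME", first),
                ("LAST_NAME", last),
                ("EMAIL", email),
            ],
        )
    )
    mwfile.sections.append(
        _kv(
            "SUBJECT",
            [
                ("SUBJECT_TYPE", rng.choice(_SUBJECT_TYPES)),
                ("SUBJECT_SPECIES", species),
            ],
        )
    )
    samples = [f"{analysis_id}-S{i + 1:02d}" for i in range(n_samples)]
    factors = [rng.choice(_FACTORS) for _ in samples]
    ssf = Section(name="SUBJECT_SAMPLE_FACTORS", kind=SectionKind.FACTOR_LIST)
    for sample, factor in zip(samples, factors):
        ssf.factor_rows.append(
            FactorRow(
                subject=f"SU-{rng.randint(1, 99):04d}",
                sample=sample,
                factors=f"Group:{factor}",
                additional=f"RAW_FILE={sample}.raw",
            )
        )
    mwfile.sections.append(ssf)
    mwfile.sections.append(
        _kv("COLLECTION", [("COLLECTION_SUMMARY", "Plasma collected after overnight fast")])
    )
    mwfile.sections.append(
        _kv("TREATMENT", [("TREATMENT_SUMMARY", "Single-dose treatment versus vehicle")])
    )
    mwfile.sections.append(
        _kv(
            "SAMPLEPREP",
            [("SAMPLEPREP_SUMMARY", "Methanol extraction, dried and reconstituted")],
        )
    )
    mwfile.sections.append(
        _kv("ANALYSIS", [("ANALYSIS_TYPE", analysis_type)])
    )
    if analysis_type == "MS":
        mwfile.sections.append(
            _kv(
                "CHROMATOGRAPHY",
                [
                    ("CHROMATOGRAPHY_TYPE", "Reversed phase"),
                    ("INSTRUMENT_NAME", rng.choice(_MS_INSTRUMENTS)),
                    ("COLUMN_NAME", rng.choice(_COLUMNS)),
                ],
            )
        )
        mwfile.sections.append(
            _kv(
                "MS",
                [
                    ("INSTRUMENT_NAME", rng.choice(_MS_INSTRUMENTS)),
                    ("INSTRUMENT_TYPE", "QTOF"),
                    ("MS_TYPE", "ESI"),
                    ("ION_MODE", rng.choice(["POSITIVE", "NEGATIVE"])),
                ],
            )
        )
        block_name = "MS_METABOLITE_DATA"
    else:
        mwfile.sections.append(
            _kv(
                "NMR",
                [
                    ("INSTRUMENT_NAME", rng.choice(_NMR_INSTRUMENTS)),
                    ("INSTRUMENT_TYPE", "FT-NMR"),
                    ("NMR_EXPERIMENT_TYPE", "1D 1H"),
                ],
            )
        )
        block_name = "NMR_METABOLITE_DATA"

    names = rng.sample(_METABOLITES, min(n_metabolites, len(_METABOLITES)))
    while len(names) < n_metabolites:
        names.append(f"feature_{len(names) + 1:03d}")
    matrix = DataMatrix(
        sample_names=list(samples),
        factor_labels=[f"Group:{f}" for f in factors],
        rows=[
            (name, [f"{rng.uniform(0.5, 50000.0):.4f}" for _ in samples])
            for name in names
        ],
    )
    mwfile.sections.append(
        Section(name=block_name, kind=SectionKind.DATA_MATRIX, matrix=matrix)
    )
    return mwfile


# --------------------------------------------------------------------------
# defect injection

ABSENT = None  # sentinel: the artifact does not exist at the source


class GenerationError(RuntimeError):
    """Defect inapplicable to the file's shape (e.g. more mutations than keys)."""


def _schema_key_pool(mwfile: MWTabFile) -> list[tuple[str, str]]:
    """Required (section, key) pairs present in the file, deletion-safe:
    removing any one of them produces exactly one validation issue."""
    schema = load_schema("1.5")
    pool = []
    for section in mwfile.sections:
        rule = schema.section_rules.get(section.name)
        if rule is None:
            continue
        keys = set(section.keys())
        for key in rule.required_keys:
            if key in keys:
                pool.append((section.name, key))
    return pool


def _delete_keys(mwfile: MWTabFile, targets: list[tuple[str, str]]) -> MWTabFile:
    mutated = copy.deepcopy(mwfile)
    for section_name, key in targets:
        section = mutated.section(section_name)
        section.items = [(k, v) for k, v in section.items if k != key]
    return mutated


def _drift_values(mwfile: MWTabFile, count: int, rng: random.Random) -> MWTabFile:
    """Alter ``count`` distinct value slots; each yields one discrepancy."""
    slots: list[tuple] = []
    for si, section in enumerate(mwfile.sections):
        if section.kind is SectionKind.DATA_MATRIX and section.matrix is not None:
            for ri, (_, values) in enumerate(section.matrix.rows):
                for ci in range(len(values)):
                    slots.append(("cell", si, ri, ci))
        elif section.kind is SectionKind.KEY_VALUE:
            for ki, (key, _) in enumerate(section.items):
                # ANALYSIS_TYPE is interpreted by the validator; drifting it
                # would change the file's validity, not just its consistency
                if key != "ANALYSIS_TYPE":
                    slots.append(("item", si, ki))
    if count > len(slots):
        raise GenerationError(
            f"cannot drift {count} values: only {len(slots)} slots available"
        )
    mutated = copy.deepcopy(mwfile)
    for slot in rng.sample(slots, count):
        if slot[0] == "cell":
            _, si, ri, ci = slot
            name, values = mutated.sections[si].matrix.rows[ri]
            values[ci] = values[ci] + "0"
        else:
            _, si, ki = slot
            key, value = mutated.sections[si].items[ki]
            mutated.sections[si].items[ki] = (key, value + " (amended)")
    return mutated


def _corrupt_text(text: str) -> bytes:
    """Delete the first data-block end sentinel: an unterminated block."""
    lines = text.split("\n")
    for i, line in enumerate(lines):
        if line.endswith("_END") and not line.startswith("#"):
            del lines[i]
            return "\n".join(lines).encode("utf-8")
    # no data block to corrupt: break the header instead
    return "\n".join(lines[1:]).encode("utf-8")


def _corrupt_json(text: str) -> bytes:
    return text[: max(1, len(text) // 2)].encode("utf-8")


def apply_defect(
    mwfile: MWTabFile, spec: DefectSpec, seed: int
) -> tuple[bytes | None, bytes | None]:
    """Serialize the pair with the defect injected.

    Returns (text bytes, JSON bytes); ``None`` marks an artifact that is
    absent at the source (distinct from a zero-byte blank file).
    """
    rng = random.Random(seed)
    defect = spec.defect
    text_file, json_file = mwfile, mwfile

    if defect in (Defect.SCHEMA_TEXT, Defect.SCHEMA_JSON, Defect.SCHEMA_BOTH):
        pool = sorted(_schema_key_pool(mwfile))
        if spec.mutation_count > len(pool):
            raise GenerationError(
                f"cannot delete {spec.mutation_count} required keys: "
                f"only {len(pool)} present"
            )
        targets = rng.sample(pool, spec.mutation_count)
        mutated = _delete_keys(mwfile, targets)
        if defect in (Defect.SCHEMA_TEXT, Defect.SCHEMA_BOTH):
            text_file = mutated
        if defect in (Defect.SCHEMA_JSON, Defect.SCHEMA_BOTH):
            json_file = mutated
    elif defect is Defect.VALUE_DRIFT:
        json_file = _drift_values(mwfile, spec.mutation_count, rng)

    text = write_mwtab_text(text_file).encode("utf-8")
    jsn = write_mwtab_json(json_file).encode("utf-8")

    if defect is Defect.MISSING_TEXT:
        return ABSENT, jsn
    if defect is Defect.MISSING_JSON:
        return text, ABSENT
    if defect is Defect.MISSING_BOTH:
        return ABSENT, ABSENT
    if defect is Defect.BLANK_TEXT:
        return b"", jsn
    if defect is Defect.GROSS_TEXT:
        return _corrupt_text(text.decode("utf-8")), jsn
    if defect is Defect.GROSS_JSON:
        return text, _corrupt_json(jsn.decode("utf-8"))
    return text, jsn


# --------------------------------------------------------------------------
# corpus generation

DEFAULT_MIX: dict[DefectSpec, float] = {
    DefectSpec(Defect.NONE): 0.40,
    DefectSpec(Defect.MISSING_TEXT): 0.03,
    DefectSpec(Defect.MISSING_JSON): 0.03,
    DefectSpec(Defect.MISSING_BOTH): 0.02,
    DefectSpec(Defect.BLANK_TEXT): 0.04,
    DefectSpec(Defect.GROSS_TEXT): 0.08,
    DefectSpec(Defect.GROSS_JSON): 0.05,
    DefectSpec(Defect.SCHEMA_TEXT, 2): 0.10,
    DefectSpec(Defect.SCHEMA_JSON, 2): 0.10,
    DefectSpec(Defect.SCHEMA_BOTH, 1): 0.05,
    DefectSpec(Defect.VALUE_DRIFT, 3): 0.10,
}


def allocate_mix(defect_mix: dict[DefectSpec, float], n: int) -> dict[DefectSpec, int]:
    """Largest-remainder apportionment of ``n`` analyses over the mix.

    Ties on the remainder are broken by defect enum order, then by
    mutation_count, so the allocation is exact and deterministic.
    """
    total = sum(defect_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"defect-mix proportions sum to {total}, not 1")
    order = list(Defect)
    specs = sorted(
        defect_mix, key=lambda s: (order.index(s.defect), s.mutation_count)
    )
    counts = {s: int(n * defect_mix[s]) for s in specs}
    remainders = {s: n * defect_mix[s] - counts[s] for s in specs}
    shortfall = n - sum(counts.values())
    for s in sorted(
        specs,
        key=lambda s: (-remainders[s], order.index(s.defect), s.mutation_count),
    )[:shortfall]:
        counts[s] += 1
    return counts


def generate_corpus(
    seed: int,
    n_studies: int,
    defect_mix: dict[DefectSpec, float] | None = None,
    output_dir: str | Path = ".",
    n_analyses: int | None = None,
) -> DefectManifest:
    """Write a reproducible corpus plus its ground-truth manifest.

    Analyses are distributed over ``n_studies`` studies in contiguous blocks
    (default two analyses per study); the whole corpus — content, defect
    assignment and bytes — is a pure function of ``seed`` and parameters.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    if defect_mix is None:
        defect_mix = DEFAULT_MIX
    if n_analyses is None:
        n_analyses = 2 * n_studies
    if n_analyses < n_studies:
        raise ValueError("need at least one analysis per study")

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    counts = allocate_mix(defect_mix, n_analyses)
    assignment: list[DefectSpec] = []
    for spec in counts:
        assignment.extend([spec] * counts[spec])
    rng = random.Random(seed)
    rng.shuffle(assignment)

    manifest = DefectManifest(seed=seed)
    for i in range(n_analyses):
        study_idx = i * n_studies // n_analyses
        study_id = f"ST{study_idx + 1:06d}"
        analysis_id = f"AN{i + 1:06d}"
        spec = assignment[i]
        file_seed = rng.randrange(2**31)
        analysis_type = "MS" if rng.random() < 0.7 else "NMR"
        mwfile = generate_valid_analysis(
            file_seed,
            study_id,
            analysis_id,
            analysis_type=analysis_type,
            n_samples=rng.randint(4, 10),
            n_metabolites=rng.randint(8, 24),
        )
        text, jsn = apply_defect(mwfile, spec, rng.randrange(2**31))
        study_dir = out / study_id
        study_dir.mkdir(exist_ok=True)
        if text is not ABSENT:
            (study_dir / f"{analysis_id}.txt").write_bytes(text)
        if jsn is not ABSENT:
            (study_dir / f"{analysis_id}.json").write_bytes(jsn)
        expected = EXPECTED_OUTCOMES[spec.defect]
        manifest.entries[analysis_id] = ManifestEntry(
            study_id=study_id,
            analysis_id=analysis_id,
            spec=spec,
            expected_text_status=expected[0],
            expected_json_status=expected[1],
            expected_comparison=expected[2],
        )
    manifest.save(out / MANIFEST_FILENAME)
    return manifest
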