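"""Public assembly-record metadata: parsing, strain labels, completeness audit.

Handles the two NCBI metadata dialects — the tab-delimited
``assembly_summary`` index (one row per assembly) and the per-assembly
``assembly_report`` key-value file — plus records produced by the
simulator.  Field names are matched case-insensitively with punctuation
stripped, since the two dialects spell the same field differently
("Sequencing technology:" vs "sequencing_technology").
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence

__all__ = [
    "MetadataRecord",
    "StrainLabel",
    "FieldCompleteness",
    "parse_summary",
    "parse_report",
    "is_empty_value",
    "audit_completeness",
    "extract_strain_labels",
    "select_atcc_records",
    "find_duplicates",
    "flag_type_material_conflicts",
    "read_synonym_table",
    "normalize_field_name",
]

#: values treated as "empty" in the completeness audit (after trim+casefold)
EMPTY_VALUES = frozenset(
    {"", "na", "n/a", "unknown", "missing", "not provided", "not applicable",
     "none", "other"}
)

#: fields scanned for culture-collection strain labels
STRAIN_LABEL_FIELDS = (
    "organism_name", "infraspecific_name", "isolate", "asm_name",
    "title", "description", "strain",
)

_STRAIN_RE = re.compile(r"\b(ATCC|NCTC)[\s\-_]*(\d{1,6}[A-Za-z]?)\b", re.IGNORECASE)
_PUNCT_RE = re.compile(r"[^a-z0-9]+")


def normalize_field_name(name: str) -> str:
    """Canonical field key: casefolded with punctuation/whitespace stripped."""
    return _PUNCT_RE.sub(" ", name.strip().casefold()).strip()


@dataclass
class MetadataRecord:
    """One public assembly record: accession plus raw descriptor fields."""

    accession: str
    fields: Dict[str, str] = field(default_factory=dict)
    source_dialect: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        self._norm = {normalize_field_name(k): v for k, v in self.fields.items()}

    def get(self, field_name: str, default: str | None = None) -> str | None:
        """Raw value for a field, matched under name normalization."""
        return self._norm.get(normalize_field_name(field_name), default)

    def has_field(self, field_name: str) -> bool:
        return normalize_field_name(field_name) in self._norm


@dataclass(frozen=True)
class StrainLabel:
    collection: str  # ATCC or NCTC
    number: str

    @property
    def normalized_key(self) -> str:
        return f"{self.collection} {self.number}"


@dataclass(frozen=True)
class FieldCompleteness:
    field: str
    n_records: int
    n_empty: int

    @property
    def fraction_empty(self) -> float:
        return self.n_empty / self.n_records if self.n_records else 0.0


def parse_summary(table_text: str, dialect: str = "summary_row") -> List[MetadataRecord]:
    """Parse an assembly_summary-style tab-delimited table.

    The header row may carry a leading ``#``.  Ragged rows raise a
    ``ValueError`` naming the offending line number.
    """
    lines = [ln for ln in table_text.splitlines()]
    header: Sequence[str] | None = None
    header_line = 0
    records: List[MetadataRecord] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if header is None:
            header = line.lstrip("#").strip("\n").split("\t")
            header = [h.strip() for h in header]
            header_line = lineno
            continue
        if line.startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ValueError(
                f"line {lineno}: expected {len(header)} columns "
                f"(header at line {header_line}), got {len(cells)}"
            )
        row = dict(zip(header, cells))
        accession = (
            row.get("assembly_accession")
            or row.get("# assembly_accession")
            or cells[0]
        )
        records.append(MetadataRecord(accession, row, source_dialect=dialect))
    if header is None:
        raise ValueError("no header row found")
    return records


def parse_report(report_text: str, accession: str | None = None) -> MetadataRecord:
    """Parse an assembly_report-style ``# key: value`` file."""
    fields: Dict[str, str] = {}
    for line in report_text.splitlines():
        line = line.lstrip("#").strip()
        if not line or ":" not in line:
            continue
        key, _, value = line.partition(":")
        fields[key.strip()] = value.strip()
    acc = accession or fields.get("Assembly name") or fields.get("GenBank assembly accession")
    for key, value in fields.items():
        if normalize_field_name(key) in ("refseq assembly accession", "assembly accession"):
            acc = value
            break
    if not acc:
        raise ValueError("assembly report carries no accession")
    return MetadataRecord(acc, fields, source_dialect="report_file")


def is_empty_value(raw: str, lexicon: frozenset[str] | set[str] = EMPTY_VALUES) -> bool:
    """True when a raw field value counts as missing for the audit."""
    return raw.strip().casefold() in lexicon


def audit_completeness(
    records: Sequence[MetadataRecord],
    fields: Sequence[str],
    lexicon: frozenset[str] | set[str] = EMPTY_VALUES,
) -> List[FieldCompleteness]:
    """Per-field emptiness over a record set.

    A field absent from a record counts as empty, matching how public
    records simply omit descriptor lines they never filled in.
    """
    if not fields:
        raise ValueError("fields must be non-empty")
    out = []
    for f in fields:
        n_empty = sum(
            1
            for r in records
            if (v := r.get(f)) is None or is_empty_value(v, lexicon)
        )
        out.append(FieldCompleteness(field=f, n_records=len(records), n_empty=n_empty))
    return out


def extract_strain_labels(
    record: MetadataRecord, scan_fields: Sequence[str] = STRAIN_LABEL_FIELDS
) -> List[StrainLabel]:
    """Culture-collection labels found in a record's descriptor fields.

    Tolerates the separator variants seen in the wild ("ATCC 13880",
    "ATCC13880", "ATCC-13880", "ATCC_13880"); labels are deduplicated after
    normalization.
    """
    seen: Dict[str, StrainLabel] = {}
    for f in scan_fields:
        value = record.get(f)
        if not value:
            continue
        for m in _STRAIN_RE.finditer(value):
            label = StrainLabel(m.group(1).upper(), m.group(2).upper())
            seen.setdefault(label.normalized_key, label)
    return list(seen.values())


def read_synonym_table(path: str | Path) -> Dict[str, str]:
    """Read an NCTC->ATCC synonym table (two-column TSV, '#' comments)."""
    synonyms: Dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        nctc, _, atcc = line.partition("\t")
        synonyms[nctc.strip()] = atcc.strip()
    return synonyms


def select_atcc_records(
    records: Sequence[MetadataRecord],
    synonyms: Mapping[str, str] | None = None,
) -> List[MetadataRecord]:
    """Keep records traceable to an ATCC strain.

    Records carrying an ATCC label are kept outright.  NCTC-only records
    are kept only when the curated synonym table maps their NCTC key to an
    ATCC key (recorded on the output record as ``resolved_atcc``).
    Everything else is dropped.  Order is stable and the call is idempotent.
    """
    synonyms = synonyms or {}
    selected: List[MetadataRecord] = []
    for record in records:
        labels = extract_strain_labels(record)
        atcc = [l for l in labels if l.collection == "ATCC"]
        nctc = [l for l in labels if l.collection == "NCTC"]
        if atcc:
            selected.append(record)
            continue
        for label in nctc:
            resolved = synonyms.get(label.normalized_key)
            if resolved:
                out = MetadataRecord(
                    record.accession,
                    {**record.fields, "resolved_atcc": resolved},
                    source_dialect=record.source_dialect,
                )
                selected.append(out)
                break
    return selected


def find_duplicates(
    records: Sequence[MetadataRecord],
) -> Dict[str, List[str]]:
    """Strain keys claimed by two or more accessions.

    Each accession appears under every strain key it carries; only keys
    with >= 2 accessions are returned.
    """
    groups: Dict[str, List[str]] = {}
    for record in records:
        for label in extract_strain_labels(record):
            groups.setdefault(label.normalized_key, []).append(record.accession)
    return {k: v for k, v in groups.items() if len(v) >= 2}


def flag_type_material_conflicts(
    records: Sequence[MetadataRecord],
    modification_fields: Sequence[str] = ("description", "organism_name", "comment"),
    modification_pattern: str = r"genetically\s+modified|genetically\s+engineered|recombinant|mutant\s+construct",
) -> List[str]:
    """Accessions labeled as type material yet described as modified genomes.

    A record is flagged when its relation-to-type-material field is
    non-empty AND any of the configured fields matches the
    genetic-modification pattern — contradictory provenance claims.
    """
    pat = re.compile(modification_pattern, re.IGNORECASE)
    flagged = []
    for record in records:
        rel = record.get("relation_to_type_material") or record.get(
            "relation to type material"
        )
        if rel is None or is_empty_value(rel):
            continue
        for f in modification_fields:
            value = record.get(f)
            if value and pat.search(value):
                flagged.append(record.accession)
                break
    return flagged


def completeness_frame(results: Iterable[FieldCompleteness]):
    """Completeness audit as a DataFrame (fractions also as percentages)."""
    import pandas as pd

    rows = [
        {
            "field": r.field,
            "n_records": r.n_records,
            "n_empty": r.n_empty,
            "fraction_empty": r.fraction_empty,
            "percent_empty": 100.0 * r.fraction_empty,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def duplicates_report(groups: Mapping[str, List[str]]) -> str:
    """Duplicate-strain groups serialized as JSON."""
    return json.dumps(
        {k: sorted(v) for k, v in sorted(groups.items())}, indent=2
    )
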