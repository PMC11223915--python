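"""Per-lab dataset ingestion: format mapping, validation, pseudonymization.

Each laboratory submits tables in its own column layout; a LabFormatSpec
(a JSON document) maps source columns and vocabularies onto the canonical
fields. Dataset acceptance is all-or-nothing: any row-level violation
rejects the whole dataset with per-row diagnostics.
"""

from __future__ import annotations

import json
import random
import string
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .errors import (
    MetadataError,
    PseudonymSpaceExhaustedError,
    SubmissionRejectedError,
    VarShareError,
)

FIVE_TIER = ("B", "LB", "VUS", "LP", "P")

SUPPORTED_CALLERS = frozenset(
    {
        "VarScan2",
        "Strelka2",
        "GATK HaplotypeCaller",
        "GATK UnifiedGenotyper",
        "Torrent Variant Caller",
        "VarDict",
        "DNAscope",
    }
)

MIN_DEPTH_THRESHOLD = 10

PSEUDONYM_ALPHABET = string.ascii_uppercase + string.digits  # 36 characters
PSEUDONYM_LENGTHS = {"individual": 6, "family": 5}


# ---------------------------------------------------------------------------
# Lab format specification
# ---------------------------------------------------------------------------


class LabFormatSpec(BaseModel):
    """Per-laboratory mapping from source layout to canonical fields."""

    lab_id: str
    column_map: dict[str, str]  # source column -> canonical field
    value_maps: dict[str, dict[str, str]] = Field(default_factory=dict)
    date_format: str = "%Y-%m-%d"

    @field_validator("value_maps")
    @classmethod
    def _injective(cls, maps: dict[str, dict[str, str]]) -> dict[str, dict[str, str]]:
        for fieldname, vmap in maps.items():
            if len(set(vmap.values())) != len(vmap):
                raise ValueError(f"value map for {fieldname!r} is not injective")
        return maps

    @classmethod
    def from_json(cls, path: str | Path) -> "LabFormatSpec":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def canonical_columns(self) -> set[str]:
        return set(self.column_map.values())


#: canonical fields every classification dataset must provide; the variant
#: may be defined genomically (chrom/pos/ref/alt) or as cdna + transcript.
CLASSIFICATION_MANDATORY = {"classification", "date"}
GENOMIC_FIELDS = {"chrom", "pos", "ref", "alt"}
CDNA_FIELDS = {"cdna", "transcript"}

INDIVIDUAL_MANDATORY = {"individual_id", "sex", "suspicion"}
INDIVIDUAL_OPTIONAL = {"family_id", "cancer_history", "birth_date", "deceased"}


@dataclass(frozen=True)
class ClassificationSubmission:
    """One canonicalized classification row."""

    lab_id: str
    classification: str
    date: date
    variant_key: str = ""  # chrom:pos:ref:alt when defined genomically
    cdna: str | None = None
    transcript: str | None = None
    reasoning: str = ""
    submitter_name: str = ""
    submitter_email: str = ""


@dataclass(frozen=True)
class IndividualSubmission:
    individual_id: str
    sex: str
    suspicion: str
    family_id: str | None = None
    cancer_history: str | None = None
    birth_date: date | None = None
    deceased: bool | None = None


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path, dtype=str)
    return pd.read_csv(path, sep="\t", dtype=str)


def _canonicalize(frame: pd.DataFrame, spec: LabFormatSpec) -> pd.DataFrame:
    missing = [src for src in spec.column_map if src not in frame.columns]
    if missing:
        raise SubmissionRejectedError(
            f"dataset from {spec.lab_id}: missing mapped columns {missing}"
        )
    out = frame.rename(columns=spec.column_map)[list(spec.column_map.values())]
    return out


def _map_value(spec: LabFormatSpec, fieldname: str, raw: str, rownum: int,
               diagnostics: list[str]) -> str | None:
    vmap = spec.value_maps.get(fieldname)
    if vmap is None:
        return raw
    if raw in vmap:
        return vmap[raw]
    diagnostics.append(f"row {rownum}: unmappable {fieldname} value {raw!r}")
    return None


def parse_classifications(
    path: str | Path, spec: LabFormatSpec
) -> list[ClassificationSubmission]:
    """Parse one lab's classification table into canonical records.

    Rows violating the vocabulary or date format are collected as
    diagnostics; any such row rejects the entire dataset.
    """
    frame = _canonicalize(_read_table(path), spec)
    canonical = spec.canonical_columns()
    missing = CLASSIFICATION_MANDATORY - canonical
    if missing:
        raise SubmissionRejectedError(
            f"dataset from {spec.lab_id}: unmapped mandatory fields {sorted(missing)}"
        )
    if not (GENOMIC_FIELDS <= canonical or CDNA_FIELDS <= canonical):
        raise SubmissionRejectedError(
            f"dataset from {spec.lab_id}: no variant definition mapped "
            "(need chrom/pos/ref/alt or cdna/transcript)"
        )

    diagnostics: list[str] = []
    records: list[ClassificationSubmission] = []
    for rownum, row in enumerate(frame.to_dict("records"), start=2):
        label = _map_value(spec, "classification", str(row["classification"]), rownum,
                           diagnostics)
        if label is not None and label not in FIVE_TIER:
            diagnostics.append(f"row {rownum}: classification {label!r} not in five-tier set")
            label = None
        parsed_date = None
        try:
            parsed_date = datetime.strptime(str(row["date"]), spec.date_format).date()
        except ValueError:
            diagnostics.append(f"row {rownum}: unparseable date {row['date']!r}")
        variant_key = ""
        if GENOMIC_FIELDS <= canonical:
            try:
                variant_key = (
                    f"{row['chrom']}:{int(row['pos'])}:"
                    f"{str(row['ref']).upper()}:{str(row['alt']).upper()}"
                )
            except (ValueError, TypeError):
                diagnostics.append(f"row {rownum}: bad genomic definition")
        if label is None or parsed_date is None:
            continue
        records.append(
            ClassificationSubmission(
                lab_id=spec.lab_id,
                classification=label,
                date=parsed_date,
                variant_key=variant_key,
                cdna=str(row["cdna"]) if "cdna" in canonical else None,
                transcript=str(row["transcript"]) if "transcript" in canonical else None,
                reasoning=str(row.get("reasoning", "") or ""),
                submitter_name=str(row.get("submitter_name", "") or ""),
                submitter_email=str(row.get("submitter_email", "") or ""),
            )
        )
    if diagnostics:
        raise SubmissionRejectedError(
            f"dataset from {spec.lab_id} rejected ({len(diagnostics)} bad rows)",
            diagnostics,
        )
    return records


def parse_individuals(
    path: str | Path, spec: LabFormatSpec, suspicion_terms: Sequence[str]
) -> list[IndividualSubmission]:
    """Parse one lab's individual-metadata table.

    Clinical suspicion is validated against the configured ontology term
    list; individual id, sex and suspicion are mandatory.
    """
    frame = _canonicalize(_read_table(path), spec)
    canonical = spec.canonical_columns()
    missing = INDIVIDUAL_MANDATORY - canonical
    if missing:
        raise SubmissionRejectedError(
            f"dataset from {spec.lab_id}: unmapped mandatory fields {sorted(missing)}"
        )
    terms = set(suspicion_terms)
    diagnostics: list[str] = []
    records: list[IndividualSubmission] = []
    for rownum, row in enumerate(frame.to_dict("records"), start=2):
        individual_id = str(row["individual_id"] or "").strip()
        if not individual_id or individual_id == "nan":
            diagnostics.append(f"row {rownum}: empty individual id")
            continue
        sex = _map_value(spec, "sex", str(row["sex"]), rownum, diagnostics)
        suspicion = _map_value(spec, "suspicion", str(row["suspicion"]), rownum, diagnostics)
        if suspicion is not None and suspicion not in terms:
            diagnostics.append(f"row {rownum}: suspicion {suspicion!r} not a known term")
            suspicion = None
        birth = None
        if "birth_date" in canonical and str(row.get("birth_date") or "") not in ("", "nan"):
            try:
                birth = datetime.strptime(str(row["birth_date"]), spec.date_format).date()
            except ValueError:
                diagnostics.append(f"row {rownum}: unparseable birth date")
        if sex is None or suspicion is None:
            continue
        family = str(row.get("family_id") or "").strip() or None
        if family == "nan":
            family = None
        deceased_raw = str(row.get("deceased") or "").strip().lower()
        deceased = {"1": True, "true": True, "yes": True, "0": False, "false": False,
                    "no": False}.get(deceased_raw)
        records.append(
            IndividualSubmission(
                individual_id=individual_id,
                sex=sex,
                suspicion=suspicion,
                family_id=family,
                cancer_history=str(row.get("cancer_history") or "") or None,
                birth_date=birth,
                deceased=deceased,
            )
        )
    if diagnostics:
        raise SubmissionRejectedError(
            f"dataset from {spec.lab_id} rejected ({len(diagnostics)} bad rows)",
            diagnostics,
        )
    return records


# ---------------------------------------------------------------------------
# Pseudonymization
# ---------------------------------------------------------------------------


@dataclass
class PseudonymMap:
    """Bidirectional source-id <-> pseudonym mapping, one namespace per kind.

    Individual pseudonyms are 6 characters, family pseudonyms 5, drawn from
    the 36 uppercase alphanumerics.
    """

    forward: dict[tuple[str, str], str] = field(default_factory=dict)  # (kind, src) -> code
    reverse: dict[tuple[str, str], str] = field(default_factory=dict)  # (kind, code) -> src

    def pseudonymize(self, source_id: str, kind: str, rng: random.Random) -> str:
        if kind not in PSEUDONYM_LENGTHS:
            raise VarShareError(f"unknown pseudonym kind {kind!r}")
        existing = self.forward.get((kind, source_id))
        if existing is not None:
            return existing
        length = PSEUDONYM_LENGTHS[kind]
        space = len(PSEUDONYM_ALPHABET) ** length
        used = sum(1 for k, _c in self.reverse if k == kind)
        if used >= space:
            raise PseudonymSpaceExhaustedError(f"no free {kind} pseudonyms left")
        while True:
            code = "".join(rng.choice(PSEUDONYM_ALPHABET) for _ in range(length))
            if (kind, code) not in self.reverse:
                break
        self.forward[(kind, source_id)] = code
        self.reverse[(kind, code)] = source_id
        return code

    def to_json(self, path: str | Path) -> None:
        data = [
            {"kind": kind, "source": src, "pseudonym": code}
            for (kind, src), code in sorted(self.forward.items())
        ]
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PseudonymMap":
        with open(path) as fh:
            data = json.load(fh)
        pm = cls()
        for row in data:
            pm.forward[(row["kind"], row["source"])] = row["pseudonym"]
            pm.reverse[(row["kind"], row["pseudonym"])] = row["source"]
        return pm


def pseudonymize(source_id: str, kind: str, pmap: PseudonymMap, rng: random.Random) -> str:
    return pmap.pseudonymize(source_id, kind, rng)


# ---------------------------------------------------------------------------
# Dataset metadata
# ---------------------------------------------------------------------------


class DatasetMetadata(BaseModel):
    """Homogeneity metadata accompanying a dataset of individual VCFs."""

    dataset_id: str
    platform: str
    read_type: str
    panel_version: str
    panel_regions_file: str
    genome_build: str
    aligner: str
    caller: str
    depth_threshold: int

    @field_validator("caller")
    @classmethod
    def _caller_supported(cls, value: str) -> str:
        if value not in SUPPORTED_CALLERS:
            raise ValueError(f"unsupported variant caller {value!r}")
        return value

    @field_validator("depth_threshold")
    @classmethod
    def _depth_min(cls, value: int) -> int:
        if value < MIN_DEPTH_THRESHOLD:
            raise ValueError(f"depth threshold {value} below minimum {MIN_DEPTH_THRESHOLD}")
        return value

    @field_validator("genome_build", "platform", "aligner", "dataset_id")
    @classmethod
    def _non_empty(cls, value: str) -> str:
        if not value.strip():
            raise ValueError("field must be non-empty")
        return value


def validate_metadata(raw: Mapping) -> DatasetMetadata:
    """Validate dataset metadata, raising MetadataError on any violation."""
    try:
        return DatasetMetadata.model_validate(dict(raw))
    except Exception as exc:  # pydantic.ValidationError
        raise MetadataError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Version manifest
# ---------------------------------------------------------------------------


@dataclass
class DatasetManifest:
    """Incremental database version counter plus accepted-dataset log."""

    path: Path
    version: int = 0
    datasets: list[dict] = field(default_factory=list)

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        path = Path(path)
        if path.exists():
            with open(path) as fh:
                data = json.load(fh)
            return cls(path=path, version=data["version"], datasets=data["datasets"])
        return cls(path=path)

    def record(self, dataset_id: str, kind: str, n_records: int) -> int:
        self.version += 1
        self.datasets.append(
            {"dataset": dataset_id, "kind": kind, "records": n_records,
             "version": self.version}
        )
        with open(self.path, "w") as fh:
            json.dump({"version": self.version, "datasets": self.datasets}, fh, indent=2)
            fh.write("\n")
        return self.version
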