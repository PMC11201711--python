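"""Subject-level cohort data model and flat-file I/O for LDCT screening studies.

A cohort is one row per screened subject: demographics and smoking history,
the baseline plasma cell-free DNA (cfDNA) concentration in ng DNA per mL
plasma, the nodules seen at the initial low-dose CT (iLDCT), and the
screening outcome — benign on follow-up, lung cancer diagnosed at the first
round (prevalent), or lung cancer diagnosed at a later round (incident).

The on-disk format is a single UTF-8 comma-separated file, one subject per
row.  A subject's nodules are serialized into one cell as a semicolon-joined
list; within each nodule the fields follow the fixed order

    nodule_id|exam_day|mean_diameter_mm|max_diameter_mm|perp_diameter_mm|
    density|solid_component_mm|upper_lobe|spiculated

with ``|`` as the within-nodule separator and the empty string for missing
optional values.  Column names may be remapped through a schema config
(``{canonical_name: csv_column}``) loaded from YAML or JSON.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "SmokingStatus",
    "Density",
    "OutcomeClass",
    "OutcomeLabel",
    "NoduleObservation",
    "SubjectRecord",
    "SchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
    "main_nodule",
    "percent_round",
    "CFDNA_CATEGORY_EDGES",
    "SIZE_CLASS_EDGES",
    "cfdna_category",
    "size_class",
]


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class SmokingStatus(str, Enum):
    CURRENT = "current"
    FORMER = "former"


class Density(str, Enum):
    """Radiological density of a nodule: solid, part-solid (mixed), non-solid."""

    SOLID = "solid"
    PART_SOLID = "part_solid"
    NON_SOLID = "non_solid"


class OutcomeClass(str, Enum):
    BENIGN = "benign"
    PREVALENT_LC = "prevalent_lc"
    INCIDENT_LC = "incident_lc"


class SchemaError(ValueError):
    """A required column is missing or the schema config is malformed."""


class CohortValidationError(ValueError):
    """A record violates a cohort invariant.

    Carries the offending ``subject_id`` and ``field`` so callers can report
    the failure precisely.
    """

    def __init__(self, subject_id: str, fieldname: str, message: str):
        self.subject_id = subject_id
        self.field = fieldname
        super().__init__(f"subject {subject_id!r}, field {fieldname!r}: {message}")


@dataclass(frozen=True)
class OutcomeLabel:
    """Screening outcome of a subject.

    ``diagnosis_round`` is 1 for prevalent LC, 2-4 for incident LC, and None
    for benign.  ``histotype`` is optional ('adenocarcinoma' or 'other').
    """

    outcome_class: OutcomeClass
    diagnosis_round: int | None = None
    histotype: str | None = None

    def validate(self, subject_id: str = "?") -> None:
        c = self.outcome_class
        r = self.diagnosis_round
        if c == OutcomeClass.BENIGN and r is not None:
            raise CohortValidationError(subject_id, "diagnosis_round", "benign outcome carries no diagnosis round")
        if c == OutcomeClass.PREVALENT_LC and r != 1:
            raise CohortValidationError(subject_id, "diagnosis_round", "prevalent LC must have diagnosis_round = 1")
        if c == OutcomeClass.INCIDENT_LC and r not in (2, 3, 4):
            raise CohortValidationError(subject_id, "diagnosis_round", "incident LC must have diagnosis_round in {2, 3, 4}")
        if self.histotype is not None and self.histotype not in ("adenocarcinoma", "other"):
            raise CohortValidationError(subject_id, "histotype", f"unknown histotype {self.histotype!r}")

    @property
    def is_cancer(self) -> bool:
        return self.outcome_class is not OutcomeClass.BENIGN


@dataclass(frozen=True)
class NoduleObservation:
    """One nodule at one exam timepoint.

    ``mean_diameter_mm`` is the reading used for size classification and the
    Brock model; ``max_diameter_mm``/``perp_diameter_mm`` are the axial
    maximum and perpendicular diameters used for volume-doubling-time
    estimation and may be absent (None) when not measured.
    ``solid_component_mm`` is meaningful only for part-solid nodules.
    """

    nodule_id: str
    mean_diameter_mm: float
    exam_day: int = 0
    max_diameter_mm: float | None = None
    perp_diameter_mm: float | None = None
    density: Density = Density.SOLID
    solid_component_mm: float = 0.0
    upper_lobe: bool = False
    spiculated: bool = False

    def validate(self, subject_id: str = "?") -> None:
        nid = f"{self.nodule_id}"
        if not self.mean_diameter_mm > 0:
            raise CohortValidationError(subject_id, f"nodule {nid}: mean_diameter_mm", "must be positive")
        mx, pp = self.max_diameter_mm, self.perp_diameter_mm
        if mx is not None and not mx > 0:
            raise CohortValidationError(subject_id, f"nodule {nid}: max_diameter_mm", "must be positive")
        if pp is not None and not pp > 0:
            raise CohortValidationError(subject_id, f"nodule {nid}: perp_diameter_mm", "must be positive")
        if mx is not None and pp is not None:
            if pp > mx + 1e-12:
                raise CohortValidationError(subject_id, f"nodule {nid}: perp_diameter_mm", "perpendicular diameter exceeds maximum diameter")
            if not (pp - 1e-9 <= self.mean_diameter_mm <= mx + 1e-9):
                raise CohortValidationError(
                    subject_id,
                    f"nodule {nid}: mean_diameter_mm",
                    "mean diameter must lie between perpendicular and maximum diameters",
                )
        if self.solid_component_mm < 0:
            raise CohortValidationError(subject_id, f"nodule {nid}: solid_component_mm", "must be non-negative")
        if self.solid_component_mm > self.mean_diameter_mm + 1e-9:
            raise CohortValidationError(subject_id, f"nodule {nid}: solid_component_mm", "solid component exceeds mean diameter")
        if self.solid_component_mm > 0 and self.density is not Density.PART_SOLID:
            raise CohortValidationError(
                subject_id,
                f"nodule {nid}: solid_component_mm",
                "solid component is meaningful only for part-solid density",
            )


@dataclass(frozen=True)
class SubjectRecord:
    """One screened subject with baseline covariates, cfDNA and nodules."""

    subject_id: str
    age_years: float
    sex: Sex
    pack_years: float
    smoking_status: SmokingStatus
    family_history_lc: bool
    emphysema: bool
    cfdna_ng_ml: float
    outcome: OutcomeLabel
    nodules: tuple[NoduleObservation, ...] = ()

    def validate(self) -> None:
        sid = self.subject_id
        if not (40 <= self.age_years <= 90):
            raise CohortValidationError(sid, "age_years", f"{self.age_years} outside [40, 90]")
        if self.pack_years < 0:
            raise CohortValidationError(sid, "pack_years", "must be non-negative")
        if self.cfdna_ng_ml < 0:
            raise CohortValidationError(sid, "cfdna_ng_ml", "must be non-negative")
        self.outcome.validate(sid)
        for nod in self.nodules:
            nod.validate(sid)

    def baseline_nodules(self) -> tuple[NoduleObservation, ...]:
        """Nodules observed at the baseline exam (exam_day == 0)."""
        return tuple(n for n in self.nodules if n.exam_day == 0)


def main_nodule(record: SubjectRecord) -> NoduleObservation | None:
    """The subject's main nodule: the baseline nodule with the largest mean
    diameter, or None for a nodule-free (negative) baseline exam."""
    baseline = record.baseline_nodules()
    if not baseline:
        return None
    return max(baseline, key=lambda n: (n.mean_diameter_mm, n.nodule_id))


# ---------------------------------------------------------------------------
# CSV serialization
# ---------------------------------------------------------------------------

CANONICAL_COLUMNS = (
    "subject_id",
    "age_years",
    "sex",
    "pack_years",
    "smoking_status",
    "family_history_lc",
    "emphysema",
    "cfdna_ng_ml",
    "outcome",
    "diagnosis_round",
    "histotype",
    "nodules",
)
_REQUIRED = CANONICAL_COLUMNS[:9]

_NODULE_FIELD_ORDER = (
    "nodule_id",
    "exam_day",
    "mean_diameter_mm",
    "max_diameter_mm",
    "perp_diameter_mm",
    "density",
    "solid_component_mm",
    "upper_lobe",
    "spiculated",
)

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n", ""}


def _fmt_bool(b: bool) -> str:
    return "true" if b else "false"


def _parse_bool(cell: str, ctx: str) -> bool:
    s = cell.strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"{ctx}: cannot parse boolean from {cell!r}")


def _fmt_num(x: float | None) -> str:
    if x is None:
        return ""
    return repr(float(x)) if not float(x).is_integer() else str(int(x))


def _serialize_nodule(n: NoduleObservation) -> str:
    parts = [
        n.nodule_id,
        str(int(n.exam_day)),
        _fmt_num(n.mean_diameter_mm),
        _fmt_num(n.max_diameter_mm),
        _fmt_num(n.perp_diameter_mm),
        n.density.value,
        _fmt_num(n.solid_component_mm),
        _fmt_bool(n.upper_lobe),
        _fmt_bool(n.spiculated),
    ]
    return "|".join(parts)


def _parse_nodule(cell: str, ctx: str) -> NoduleObservation:
    parts = cell.split("|")
    if len(parts) != len(_NODULE_FIELD_ORDER):
        raise ValueError(f"{ctx}: nodule entry {cell!r} has {len(parts)} fields, expected {len(_NODULE_FIELD_ORDER)}")
    def num(s: str, name: str, optional: bool = False) -> float | None:
        s = s.strip()
        if s == "":
            if optional:
                return None
            raise ValueError(f"{ctx}: nodule field {name} is required")
        try:
            return float(s)
        except ValueError as exc:
            raise ValueError(f"{ctx}: nodule field {name}: malformed number {s!r}") from exc
    return NoduleObservation(
        nodule_id=parts[0],
        exam_day=int(num(parts[1], "exam_day")),
        mean_diameter_mm=num(parts[2], "mean_diameter_mm"),
        max_diameter_mm=num(parts[3], "max_diameter_mm", optional=True),
        perp_diameter_mm=num(parts[4], "perp_diameter_mm", optional=True),
        density=Density(parts[5]),
        solid_component_mm=num(parts[6], "solid_component_mm") if parts[6].strip() else 0.0,
        upper_lobe=_parse_bool(parts[7], ctx),
        spiculated=_parse_bool(parts[8], ctx),
    )


def load_schema(path) -> dict[str, str]:
    """Load a ``{canonical_name: csv_column}`` mapping from YAML or JSON."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise SchemaError(f"schema config {path} must be a mapping")
    unknown = set(mapping) - set(CANONICAL_COLUMNS)
    if unknown:
        raise SchemaError(f"schema config maps unknown fields: {sorted(unknown)}")
    return {str(k): str(v) for k, v in mapping.items()}


def read_cohort(path, schema: dict[str, str] | None = None) -> list[SubjectRecord]:
    """Read and validate a cohort CSV into SubjectRecords, preserving row order.

    ``schema`` optionally remaps canonical field names to CSV column names.
    Raises SchemaError for missing required columns and CohortValidationError
    (with subject id and field) for invariant violations; malformed numeric
    cells raise ValueError naming the data row index.
    """
    schema = schema or {}
    colname = {canon: schema.get(canon, canon) for canon in CANONICAL_COLUMNS}

    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        missing = [colname[c] for c in _REQUIRED if colname[c] not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required columns {missing}")
        records: list[SubjectRecord] = []
        for i, row in enumerate(reader):
            ctx = f"row {i}"
            def cell(canon: str, default: str = "") -> str:
                return (row.get(colname[canon]) or default).strip()

            sid = cell("subject_id")
            try:
                rnd_s = cell("diagnosis_round")
                hist = cell("histotype") or None
                outcome = OutcomeLabel(
                    outcome_class=OutcomeClass(cell("outcome")),
                    diagnosis_round=int(rnd_s) if rnd_s else None,
                    histotype=hist,
                )
                nod_cell = cell("nodules")
                nodules = tuple(
                    _parse_nodule(part, ctx) for part in nod_cell.split(";") if part.strip()
                )
                record = SubjectRecord(
                    subject_id=sid,
                    age_years=float(cell("age_years")),
                    sex=Sex(cell("sex")),
                    pack_years=float(cell("pack_years")),
                    smoking_status=SmokingStatus(cell("smoking_status")),
                    family_history_lc=_parse_bool(cell("family_history_lc"), ctx),
                    emphysema=_parse_bool(cell("emphysema"), ctx),
                    cfdna_ng_ml=float(cell("cfdna_ng_ml")),
                    outcome=outcome,
                    nodules=nodules,
                )
            except CohortValidationError:
                raise
            except (ValueError, KeyError) as exc:
                logger.error("cohort %s, %s (subject %r): %s", path, ctx, sid, exc)
                raise ValueError(f"{path}, {ctx} (subject {sid!r}): {exc}") from exc
            try:
                record.validate()
            except CohortValidationError:
                logger.error("cohort %s, %s: validation failed for subject %r", path, ctx, sid)
                raise
            records.append(record)
    return records


def write_cohort(records: Sequence[SubjectRecord], path) -> None:
    """Write validated records as a cohort CSV readable by :func:`read_cohort`."""
    for rec in records:
        rec.validate()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CANONICAL_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.subject_id,
                    _fmt_num(rec.age_years),
                    rec.sex.value,
                    _fmt_num(rec.pack_years),
                    rec.smoking_status.value,
                    _fmt_bool(rec.family_history_lc),
                    _fmt_bool(rec.emphysema),
                    _fmt_num(rec.cfdna_ng_ml),
                    rec.outcome.outcome_class.value,
                    "" if rec.outcome.diagnosis_round is None else str(rec.outcome.diagnosis_round),
                    rec.outcome.histotype or "",
                    ";".join(_serialize_nodule(n) for n in rec.nodules),
                ]
            )


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------

CFDNA_CATEGORY_EDGES = (3.15, 5.0)
CFDNA_CATEGORY_LABELS = ("<3.15", "3.15-<5", ">=5")
SIZE_CLASS_EDGES = (6.0, 8.0, 15.0)
SIZE_CLASS_LABELS = ("<6", "6-<8", "8-<15", ">=15")


def cfdna_category(value: float) -> str:
    """Half-open cfDNA concentration category: <3.15, [3.15, 5), >=5 ng/mL."""
    if value < CFDNA_CATEGORY_EDGES[0]:
        return CFDNA_CATEGORY_LABELS[0]
    if value < CFDNA_CATEGORY_EDGES[1]:
        return CFDNA_CATEGORY_LABELS[1]
    return CFDNA_CATEGORY_LABELS[2]


def size_class(diameter_mm: float) -> str:
    """Half-open main-nodule size class in mm: <6, [6, 8), [8, 15), >=15."""
    for edge, label in zip(SIZE_CLASS_EDGES, SIZE_CLASS_LABELS):
        if diameter_mm < edge:
            return label
    return SIZE_CLASS_LABELS[-1]


def percent_round(fraction: float) -> int:
    """Round a proportion to integer percent, half-up (0.148 -> 15)."""
    return int(math.floor(fraction * 100.0 + 0.5))


def summarize_cohort(records: Sequence[SubjectRecord]) -> dict[str, dict]:
    """Per-outcome-group descriptive statistics.

    Returns ``{group: {...}}`` with n, mean age, median pack-years, mean
    cfDNA, binary-covariate counts, cfDNA-category counts, main-nodule size
    class counts, nodule-count distribution and Lung-RADS category counts.
    Counts are additive under cohort concatenation and invariant under row
    permutation.
    """
    import numpy as np

    from .lungrads import classify_lungrads  # local import: lungrads depends on cohort types

    if not records:
        raise ValueError("summarize_cohort requires a nonempty cohort")
    out: dict[str, dict] = {}
    for group in OutcomeClass:
        members = [r for r in records if r.outcome.outcome_class is group]
        if not members:
            continue
        ages = np.array([r.age_years for r in members])
        packs = np.array([r.pack_years for r in members])
        cfd = np.array([r.cfdna_ng_ml for r in members])
        cf_counts = {label: 0 for label in CFDNA_CATEGORY_LABELS}
        for r in members:
            cf_counts[cfdna_category(r.cfdna_ng_ml)] += 1
        size_counts = {label: 0 for label in SIZE_CLASS_LABELS}
        size_counts["no_nodule"] = 0
        nod_counts: dict[str, int] = {"0": 0, "1": 0, "2": 0, ">=3": 0}
        lr_counts: dict[str, int] = {}
        spiculated_n = 0
        for r in members:
            mn = main_nodule(r)
            if mn is None:
                size_counts["no_nodule"] += 1
            else:
                size_counts[size_class(mn.mean_diameter_mm)] += 1
            k = len(r.baseline_nodules())
            nod_counts[str(k) if k < 3 else ">=3"] += 1
            if any(n.spiculated for n in r.baseline_nodules()):
                spiculated_n += 1
            cat = classify_lungrads(r.baseline_nodules()).value
            lr_counts[cat] = lr_counts.get(cat, 0) + 1
        out[group.value] = {
            "n": len(members),
            "age_mean": float(ages.mean()),
            "pack_years_median": float(np.median(packs)),
            "cfdna_mean": float(cfd.mean()),
            "female_n": sum(r.sex is Sex.FEMALE for r in members),
            "current_smoker_n": sum(r.smoking_status is SmokingStatus.CURRENT for r in members),
            "family_history_n": sum(r.family_history_lc for r in members),
            "emphysema_n": sum(r.emphysema for r in members),
            "spiculation_n": spiculated_n,
            "cfdna_categories": cf_counts,
            "size_classes": size_counts,
            "nodule_counts": nod_counts,
            "lungrads": dict(sorted(lr_counts.items())),
        }
    return out
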