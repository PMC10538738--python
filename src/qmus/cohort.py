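"""Cohort data model: subjects, muscle identifiers, and delimited-text I/O.

One row per subject; missing cells stay missing (they are never coerced to
zero).  Validation is total: any malformed input raises
:class:`CohortValidationError` with row/column coordinates and no partially
loaded table escapes.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional

__all__ = [
    "MuscleId",
    "Group",
    "Sex",
    "Side",
    "CONTRACTED_CAPABLE",
    "PROXIMAL_MUSCLES",
    "MRC_MOVEMENTS",
    "CLINICAL_SCALE_RANGES",
    "SubjectRecord",
    "CohortTable",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "COHORT_COLUMNS",
]


class MuscleId(str, Enum):
    """The eight muscles studied sonographically.

    The value of each member is the short token used in file columns
    (e.g. ``rel_biceps``, ``fasc_edb``).
    """

    BICEPS = "biceps"
    FDI = "fdi"
    APB = "apb"
    ADM = "adm"
    QUADRICEPS = "quad"
    TIBIALIS_ANTERIOR = "ta"
    AHB = "ahb"
    EDB = "edb"


#: Muscles for which contracted thickness is measured.
CONTRACTED_CAPABLE = frozenset(
    {MuscleId.BICEPS, MuscleId.APB, MuscleId.QUADRICEPS, MuscleId.TIBIALIS_ANTERIOR}
)

#: Proximal muscles used by the proximal fasciculation rule.
PROXIMAL_MUSCLES = frozenset({MuscleId.BICEPS, MuscleId.QUADRICEPS})


class Group(str, Enum):
    CONTROL = "CONTROL"
    MYO = "MYO"
    PNP = "PNP"
    ALS = "ALS"
    SMA = "SMA"


class Sex(str, Enum):
    F = "F"
    M = "M"


class Side(str, Enum):
    RIGHT = "RIGHT"
    LEFT = "LEFT"


#: The ten manually tested movements, in file-column order.
MRC_MOVEMENTS = (
    "shoulder_abd",
    "elbow_flex",
    "elbow_ext",
    "finger_abd",
    "finger_ext",
    "hip_flex",
    "knee_ext",
    "dorsiflex",
    "plantarflex",
    "bigtoe_ext",
)

#: Valid value ranges for known clinical scales.
CLINICAL_SCALE_RANGES = {"ALSFRS-R": (0.0, 48.0), "HFMSE": (0.0, 69.0)}

# Fixed column schema of the cohort file.
_RELAXED_COLS = tuple(f"rel_{m.value}" for m in MuscleId)
_CONTRACTED_COLS = tuple(
    f"con_{m.value}" for m in MuscleId if m in CONTRACTED_CAPABLE
)
_FASC_COLS = tuple(f"fasc_{m.value}" for m in MuscleId)
_MRC_COLS = tuple(f"mrc_{mv}" for mv in MRC_MOVEMENTS)

COHORT_COLUMNS = (
    ("subject_id", "group", "age", "sex", "bmi", "disease_duration", "side")
    + _RELAXED_COLS
    + _CONTRACTED_COLS
    + _FASC_COLS
    + _MRC_COLS
    + ("clinical_scale_name", "clinical_scale_value")
)


class CohortValidationError(ValueError):
    """Raised when a cohort table or file violates the schema.

    Carries optional 1-based ``row`` and ``column`` coordinates pointing at
    the offending cell of the source file.
    """

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = ""
        if row is not None:
            loc += f" [row {row}"
            if column is not None:
                loc += f", column '{column}'"
            loc += "]"
        super().__init__(message + loc)
        self.row = row
        self.column = column


@dataclass
class SubjectRecord:
    """One subject: demographics plus per-muscle observations.

    Thickness maps hold centimetres; absent keys mean the muscle was not
    measured.  ``fasciculation_present`` records whether any fasciculation
    was seen in the muscle during the scan window.
    """

    subject_id: str
    group: Group
    age: float
    sex: Sex
    side: Side = Side.RIGHT
    bmi: Optional[float] = None
    disease_duration: Optional[float] = None
    relaxed_thickness: dict[MuscleId, float] = field(default_factory=dict)
    contracted_thickness: dict[MuscleId, float] = field(default_factory=dict)
    fasciculation_present: dict[MuscleId, bool] = field(default_factory=dict)
    mrc: Optional[dict[str, float]] = None
    clinical_scale_name: Optional[str] = None
    clinical_scale_value: Optional[float] = None

    def validate(
        self, row: int | None = None, warning_sink: list[str] | None = None
    ) -> None:
        """Raise :class:`CohortValidationError` on any invariant violation.

        Non-fatal oddities (contracted thinner than relaxed) are warned
        about, or appended to ``warning_sink`` when one is given so a
        caller can aggregate them.
        """
        if not self.subject_id:
            raise CohortValidationError("empty subject_id", row, "subject_id")
        if not isinstance(self.group, Group):
            raise CohortValidationError(f"unknown group {self.group!r}", row, "group")
        if not isinstance(self.sex, Sex):
            raise CohortValidationError(f"unknown sex {self.sex!r}", row, "sex")
        if not isinstance(self.side, Side):
            raise CohortValidationError(f"unknown side {self.side!r}", row, "side")
        if not self.age > 0:
            raise CohortValidationError(f"age must be positive, got {self.age}", row, "age")
        if self.bmi is not None and not self.bmi > 0:
            raise CohortValidationError(f"bmi must be positive, got {self.bmi}", row, "bmi")
        if self.disease_duration is not None:
            if self.disease_duration < 0:
                raise CohortValidationError(
                    f"disease_duration must be non-negative, got {self.disease_duration}",
                    row,
                    "disease_duration",
                )
            if self.group is Group.CONTROL:
                raise CohortValidationError(
                    "disease_duration must be absent for CONTROL subjects",
                    row,
                    "disease_duration",
                )
        for muscle, value in self.relaxed_thickness.items():
            if value < 0:
                raise CohortValidationError(
                    f"negative thickness {value}", row, f"rel_{muscle.value}"
                )
        for muscle, value in self.contracted_thickness.items():
            if muscle not in CONTRACTED_CAPABLE:
                raise CohortValidationError(
                    f"{muscle.name} is not a contracted-capable muscle",
                    row,
                    f"con_{muscle.value}",
                )
            if value < 0:
                raise CohortValidationError(
                    f"negative thickness {value}", row, f"con_{muscle.value}"
                )
        if not set(self.fasciculation_present) <= set(MuscleId):
            raise CohortValidationError("fasciculation keys outside muscle set", row)
        if self.mrc is not None:
            for movement, score in self.mrc.items():
                if movement not in MRC_MOVEMENTS:
                    raise CohortValidationError(
                        f"unknown MRC movement {movement!r}", row
                    )
                if not 0 <= score <= 5:
                    raise CohortValidationError(
                        f"MRC score out of range: {score}", row, f"mrc_{movement}"
                    )
        if (self.clinical_scale_name is None) != (self.clinical_scale_value is None):
            raise CohortValidationError(
                "clinical scale name and value must be given together",
                row,
                "clinical_scale_name",
            )
        if self.clinical_scale_name is not None:
            bounds = CLINICAL_SCALE_RANGES.get(self.clinical_scale_name)
            if bounds is not None:
                lo, hi = bounds
                if not lo <= self.clinical_scale_value <= hi:
                    raise CohortValidationError(
                        f"{self.clinical_scale_name} value {self.clinical_scale_value} "
                        f"outside [{lo}, {hi}]",
                        row,
                        "clinical_scale_value",
                    )
        # Contracted thinner than relaxed is physiologically odd but not fatal.
        for muscle in self.contracted_thickness:
            rel = self.relaxed_thickness.get(muscle)
            if rel is not None and self.contracted_thickness[muscle] < rel:
                message = (
                    f"subject {self.subject_id}: contracted {muscle.name} thickness "
                    f"{self.contracted_thickness[muscle]} < relaxed {rel}"
                )
                if warning_sink is not None:
                    warning_sink.append(message)
                else:
                    warnings.warn(message, stacklevel=2)


@dataclass
class CohortTable:
    """Ordered collection of validated subject records."""

    records: list[SubjectRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    def validate(self) -> None:
        seen: set[str] = set()
        oddities: list[str] = []
        for i, rec in enumerate(self.records):
            rec.validate(row=i + 2, warning_sink=oddities)  # +2: header is row 1
            if rec.subject_id in seen:
                raise CohortValidationError(
                    f"duplicate subject_id {rec.subject_id!r}", row=i + 2,
                    column="subject_id",
                )
            seen.add(rec.subject_id)
        if oddities:
            warnings.warn(
                f"{len(oddities)} subject(s) with contracted thickness below "
                f"relaxed (first: {oddities[0]})",
                stacklevel=2,
            )

    def by_group(self, group: Group) -> list[SubjectRecord]:
        return [r for r in self.records if r.group is group]

    def group_counts(self) -> dict[Group, int]:
        counts = {g: 0 for g in Group}
        for rec in self.records:
            counts[rec.group] += 1
        return counts


def _fmt_float(value: float, min_decimals: int = 0) -> str:
    # repr round-trips exactly; pad to the minimum displayed precision
    s = repr(float(value))
    if "e" in s or "E" in s:
        return s
    if "." not in s:
        s += ".0"
    whole, frac = s.split(".")
    if len(frac) < min_decimals:
        frac = frac.ljust(min_decimals, "0")
    return f"{whole}.{frac}"


def _parse_float(
    cell: str, row: int, column: str, *, allow_negative: bool = True
) -> Optional[float]:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        value = float(cell)
    except ValueError:
        raise CohortValidationError(f"cannot parse number {cell!r}", row, column) from None
    if not allow_negative and value < 0:
        raise CohortValidationError(f"negative value {cell!r}", row, column)
    return value


def _parse_bool(cell: str, row: int, column: str) -> Optional[bool]:
    cell = cell.strip().lower()
    if cell == "":
        return None
    if cell in {"1", "true"}:
        return True
    if cell in {"0", "false"}:
        return False
    raise CohortValidationError(f"expected 0/1/empty, got {cell!r}", row, column)


def _parse_enum(enum_cls, cell: str, row: int, column: str):
    cell = cell.strip()
    try:
        return enum_cls[cell]
    except KeyError:
        valid = ", ".join(m.name for m in enum_cls)
        raise CohortValidationError(
            f"unknown {enum_cls.__name__.lower()} label {cell!r} (expected one of {valid})",
            row,
            column,
        ) from None


def read_cohort(path: str | Path, delimiter: str | None = None) -> CohortTable:
    """Read and validate a cohort table from a delimited-text file.

    ``delimiter`` defaults to auto-detection between comma and tab based on
    the header line.  The header must match :data:`COHORT_COLUMNS` exactly.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if delimiter is None:
            delimiter = "\t" if "\t" in first else ","
        fh.seek(0)
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortValidationError("empty file: missing header", row=1) from None
        if tuple(h.strip() for h in header) != COHORT_COLUMNS:
            raise CohortValidationError(
                f"malformed header: expected columns {', '.join(COHORT_COLUMNS[:5])}, ...",
                row=1,
            )
        records: list[SubjectRecord] = []
        for row_no, row in enumerate(reader, start=2):
            if not row or all(c.strip() == "" for c in row):
                continue
            if len(row) != len(COHORT_COLUMNS):
                raise CohortValidationError(
                    f"expected {len(COHORT_COLUMNS)} fields, found {len(row)}", row=row_no
                )
            cells = dict(zip(COHORT_COLUMNS, row))
            records.append(_record_from_cells(cells, row_no))
    table = CohortTable(records=records, provenance=str(path))
    table.validate()
    return table


def _record_from_cells(cells: dict[str, str], row_no: int) -> SubjectRecord:
    relaxed: dict[MuscleId, float] = {}
    contracted: dict[MuscleId, float] = {}
    fasc: dict[MuscleId, bool] = {}
    for muscle in MuscleId:
        v = _parse_float(cells[f"rel_{muscle.value}"], row_no, f"rel_{muscle.value}",
                         allow_negative=False)
        if v is not None:
            relaxed[muscle] = v
        b = _parse_bool(cells[f"fasc_{muscle.value}"], row_no, f"fasc_{muscle.value}")
        if b is not None:
            fasc[muscle] = b
        if muscle in CONTRACTED_CAPABLE:
            v = _parse_float(cells[f"con_{muscle.value}"], row_no, f"con_{muscle.value}",
                             allow_negative=False)
            if v is not None:
                contracted[muscle] = v
    mrc: dict[str, float] = {}
    for movement in MRC_MOVEMENTS:
        v = _parse_float(cells[f"mrc_{movement}"], row_no, f"mrc_{movement}")
        if v is not None:
            mrc[movement] = v
    scale_name = cells["clinical_scale_name"].strip() or None
    scale_value = _parse_float(cells["clinical_scale_value"], row_no, "clinical_scale_value")
    age = _parse_float(cells["age"], row_no, "age")
    if age is None:
        raise CohortValidationError("age is required", row_no, "age")
    return SubjectRecord(
        subject_id=cells["subject_id"].strip(),
        group=_parse_enum(Group, cells["group"], row_no, "group"),
        age=age,
        sex=_parse_enum(Sex, cells["sex"], row_no, "sex"),
        side=_parse_enum(Side, cells["side"], row_no, "side"),
        bmi=_parse_float(cells["bmi"], row_no, "bmi"),
        disease_duration=_parse_float(cells["disease_duration"], row_no, "disease_duration"),
        relaxed_thickness=relaxed,
        contracted_thickness=contracted,
        fasciculation_present=fasc,
        mrc=mrc or None,
        clinical_scale_name=scale_name,
        clinical_scale_value=scale_value,
    )


def write_cohort(table: CohortTable, path: str | Path, delimiter: str = ",") -> None:
    """Write a validated cohort table; ``read_cohort`` round-trips it exactly."""
    table.validate()
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(COHORT_COLUMNS)
        for rec in table.records:
            writer.writerow(_record_to_cells(rec))


def _record_to_cells(rec: SubjectRecord) -> list[str]:
    def opt(value: Optional[float], min_dec: int = 0) -> str:
        return "" if value is None else _fmt_float(value, min_dec)

    cells = [
        rec.subject_id,
        rec.group.name,
        _fmt_float(rec.age),
        rec.sex.name,
        opt(rec.bmi),
        opt(rec.disease_duration),
        rec.side.name,
    ]
    for muscle in MuscleId:
        cells.append(opt(rec.relaxed_thickness.get(muscle), min_dec=2))
    for muscle in MuscleId:
        if muscle in CONTRACTED_CAPABLE:
            cells.append(opt(rec.contracted_thickness.get(muscle), min_dec=2))
    for muscle in MuscleId:
        present = rec.fasciculation_present.get(muscle)
        cells.append("" if present is None else ("1" if present else "0"))
    mrc = rec.mrc or {}
    for movement in MRC_MOVEMENTS:
        cells.append(opt(mrc.get(movement)))
    cells.append(rec.clinical_scale_name or "")
    cells.append(opt(rec.clinical_scale_value))
    return cells
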