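"""Data model and delimited-text I/O for the three record streams.

A retrospective surgical cohort is represented by three linked tables:

* **procedures** — one row per surgical procedure (peripheral lymph node or
  laparoscopic biopsy) carrying the stratum labels used in the analysis:
  SIV/SHIV infection status at the time of surgery, whether perioperative
  antibiotic prophylaxis was given, and the length of the post-operative
  observation period in days.
* **prescriptions** — dated drug orders per animal, classified into the drug
  classes whose post-operative use screens for a complication (antibiotics,
  NSAIDs, opioids).
* **notes** — dated free-text observation notes per animal.

Care events are linked to procedures purely by animal identity and a
post-operative day window: the surgery day is day 0 and the default screening
window is days 1 through 8 inclusive.  An event may attach to more than one
procedure of the same animal when observation windows overlap; procedures
sharing a date (e.g. two biopsies under one anesthetic event) both receive
the event.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ProcedureType",
    "InfectionStatus",
    "EventKind",
    "DrugClass",
    "ProcedureRecord",
    "CareEvent",
    "AnimalDemographics",
    "SchemaError",
    "RecordValidationError",
    "DEFAULT_DRUG_CLASSES",
    "classify_drug",
    "read_procedures",
    "read_prescriptions",
    "read_notes",
    "read_demographics",
    "write_procedures",
    "write_prescriptions",
    "write_notes",
    "write_demographics",
    "link_events",
]


class ProcedureType(str, Enum):
    PLN = "PLN"
    LAPAROSCOPIC = "LAPAROSCOPIC"


class InfectionStatus(str, Enum):
    INFECTED = "INFECTED"
    UNINFECTED = "UNINFECTED"


class EventKind(str, Enum):
    PRESCRIPTION = "PRESCRIPTION"
    NOTE = "NOTE"


class DrugClass(str, Enum):
    ANTIBIOTIC = "ANTIBIOTIC"
    NSAID = "NSAID"
    OPIOID = "OPIOID"
    OTHER = "OTHER"


class Species(str, Enum):
    RHESUS = "RHESUS"
    CYNOMOLGUS = "CYNOMOLGUS"


class Sex(str, Enum):
    M = "M"
    F = "F"


#: Drug-name -> class dictionary used when an input row leaves drug_class
#: blank.  Seeded with the drugs the screening criteria name; anything
#: unrecognised maps to OTHER.
DEFAULT_DRUG_CLASSES: Mapping[str, DrugClass] = {
    "cefazolin": DrugClass.ANTIBIOTIC,
    "cephalexin": DrugClass.ANTIBIOTIC,
    "meloxicam": DrugClass.NSAID,
    "carprofen": DrugClass.NSAID,
    "ketoprofen": DrugClass.NSAID,
    "buprenorphine": DrugClass.OPIOID,
    "buprenorphine sr": DrugClass.OPIOID,
}


class SchemaError(ValueError):
    """A required column is missing from a delimited-text file."""


class RecordValidationError(ValueError):
    """One or more rows failed validation; the message names each row."""


@dataclass(frozen=True)
class ProcedureRecord:
    """One surgical procedure with its stratum labels and observation window."""

    procedure_id: str
    animal_id: str
    surgery_date: dt.date
    procedure_type: ProcedureType
    infection_status: InfectionStatus
    prophylaxis: bool
    observation_days: int

    def __post_init__(self) -> None:
        if self.observation_days < 0:
            raise ValueError(
                f"observation_days must be >= 0, got {self.observation_days}"
            )


@dataclass(frozen=True)
class CareEvent:
    """A dated prescription or observation note attached to an animal."""

    animal_id: str
    event_date: dt.date
    kind: EventKind
    drug_name: str = ""
    drug_class: DrugClass | None = None
    indication: str = ""
    note_text: str = ""

    def __post_init__(self) -> None:
        if self.kind is EventKind.PRESCRIPTION and self.drug_class is None:
            raise ValueError("PRESCRIPTION events require drug_class")
        if self.kind is EventKind.NOTE and not self.note_text:
            raise ValueError("NOTE events require non-empty note_text")


@dataclass(frozen=True)
class AnimalDemographics:
    """Per-animal demographics: species, sex, age and body condition score."""

    animal_id: str
    species: Species
    sex: Sex
    age_years: float
    bcs: float

    #: plausible age range; configurable at read time
    AGE_RANGE = (0.0, 40.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.age_years <= self.AGE_RANGE[1]):
            raise ValueError(f"age_years out of range: {self.age_years}")
        if not (1.0 <= self.bcs <= 5.0):
            raise ValueError(f"bcs must lie in [1.0, 5.0], got {self.bcs}")


def classify_drug(
    name: str, drug_classes: Mapping[str, DrugClass] | None = None
) -> DrugClass:
    """Map a drug name to its class via the (configurable) dictionary."""
    table = DEFAULT_DRUG_CLASSES if drug_classes is None else drug_classes
    return table.get(name.strip().lower(), DrugClass.OTHER)


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}


def _parse_bool(raw: str) -> bool:
    v = raw.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"cannot interpret {raw!r} as boolean")


def _parse_date(raw: str) -> dt.date:
    return dt.date.fromisoformat(raw.strip())


def _parse_enum(enum_cls, raw: str):
    try:
        return enum_cls[raw.strip().upper().replace(" ", "_")]
    except KeyError:
        valid = ", ".join(m.name for m in enum_cls)
        raise ValueError(f"{raw!r} is not one of: {valid}") from None


def _check_header(reader: csv.DictReader, required: Sequence[str], path) -> None:
    have = set(reader.fieldnames or ())
    missing = [c for c in required if c not in have]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _collect(path, delimiter, required, row_parser):
    path = Path(path)
    out, errors = [], []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        _check_header(reader, required, path)
        for lineno, row in enumerate(reader, start=2):  # header is line 1
            try:
                out.append(row_parser(row))
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise RecordValidationError(
            f"{path}: {len(errors)} invalid row(s)\n" + "\n".join(errors)
        )
    return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

PROCEDURE_COLUMNS = (
    "procedure_id",
    "animal_id",
    "surgery_date",
    "procedure_type",
    "infection_status",
    "prophylaxis",
    "observation_days",
)
PRESCRIPTION_COLUMNS = ("animal_id", "event_date", "drug_name", "drug_class", "indication")
NOTE_COLUMNS = ("animal_id", "event_date", "note_text")
DEMOGRAPHICS_COLUMNS = ("animal_id", "species", "sex", "age_years", "bcs")


def read_procedures(path, delimiter: str = ",") -> list[ProcedureRecord]:
    """Read and validate procedures.csv; invalid rows are reported by line."""

    def parse(row) -> ProcedureRecord:
        obs = int(row["observation_days"])
        return ProcedureRecord(
            procedure_id=row["procedure_id"].strip(),
            animal_id=row["animal_id"].strip(),
            surgery_date=_parse_date(row["surgery_date"]),
            procedure_type=_parse_enum(ProcedureType, row["procedure_type"]),
            infection_status=_parse_enum(InfectionStatus, row["infection_status"]),
            prophylaxis=_parse_bool(row["prophylaxis"]),
            observation_days=obs,
        )

    records = _collect(path, delimiter, PROCEDURE_COLUMNS, parse)
    seen: dict[str, int] = {}
    dupes = []
    for i, rec in enumerate(records):
        if rec.procedure_id in seen:
            dupes.append(rec.procedure_id)
        seen[rec.procedure_id] = i
    if dupes:
        raise RecordValidationError(f"{path}: duplicate procedure_id(s): {dupes}")
    return records


def read_prescriptions(
    path,
    delimiter: str = ",",
    drug_classes: Mapping[str, DrugClass] | None = None,
) -> list[CareEvent]:
    """Read prescriptions.csv; blank drug_class is filled from the dictionary."""

    def parse(row) -> CareEvent:
        raw_class = (row.get("drug_class") or "").strip()
        cls = (
            _parse_enum(DrugClass, raw_class)
            if raw_class
            else classify_drug(row["drug_name"], drug_classes)
        )
        return CareEvent(
            animal_id=row["animal_id"].strip(),
            event_date=_parse_date(row["event_date"]),
            kind=EventKind.PRESCRIPTION,
            drug_name=row["drug_name"].strip(),
            drug_class=cls,
            indication=(row.get("indication") or "").strip(),
        )

    return _collect(path, delimiter, PRESCRIPTION_COLUMNS[:3], parse)


def read_notes(path, delimiter: str = ",") -> list[CareEvent]:
    def parse(row) -> CareEvent:
        return CareEvent(
            animal_id=row["animal_id"].strip(),
            event_date=_parse_date(row["event_date"]),
            kind=EventKind.NOTE,
            note_text=row["note_text"].strip(),
        )

    return _collect(path, delimiter, NOTE_COLUMNS, parse)


def read_demographics(path, delimiter: str = ",") -> list[AnimalDemographics]:
    def parse(row) -> AnimalDemographics:
        return AnimalDemographics(
            animal_id=row["animal_id"].strip(),
            species=_parse_enum(Species, row["species"]),
            sex=_parse_enum(Sex, row["sex"]),
            age_years=float(row["age_years"]),
            bcs=float(row["bcs"]),
        )

    return _collect(path, delimiter, DEMOGRAPHICS_COLUMNS, parse)


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)
# ---------------------------------------------------------------------------


def _write(path, delimiter, header, rows) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(header)
        writer.writerows(rows)


def write_procedures(path, records: Iterable[ProcedureRecord], delimiter=",") -> None:
    _write(
        path,
        delimiter,
        PROCEDURE_COLUMNS,
        (
            (
                r.procedure_id,
                r.animal_id,
                r.surgery_date.isoformat(),
                r.procedure_type.value,
                r.infection_status.value,
                int(r.prophylaxis),
                r.observation_days,
            )
            for r in records
        ),
    )


def write_prescriptions(path, events: Iterable[CareEvent], delimiter=",") -> None:
    _write(
        path,
        delimiter,
        PRESCRIPTION_COLUMNS,
        (
            (
                e.animal_id,
                e.event_date.isoformat(),
                e.drug_name,
                e.drug_class.value if e.drug_class else "",
                e.indication,
            )
            for e in events
            if e.kind is EventKind.PRESCRIPTION
        ),
    )


def write_notes(path, events: Iterable[CareEvent], delimiter=",") -> None:
    _write(
        path,
        delimiter,
        NOTE_COLUMNS,
        (
            (e.animal_id, e.event_date.isoformat(), e.note_text)
            for e in events
            if e.kind is EventKind.NOTE
        ),
    )


def write_demographics(path, demos: Iterable[AnimalDemographics], delimiter=",") -> None:
    _write(
        path,
        delimiter,
        DEMOGRAPHICS_COLUMNS,
        (
            (d.animal_id, d.species.value, d.sex.value, f"{d.age_years:.2f}", f"{d.bcs:.1f}")
            for d in demos
        ),
    )


# ---------------------------------------------------------------------------
# linkage
# ---------------------------------------------------------------------------


def link_events(
    procedures: Sequence[ProcedureRecord],
    events: Sequence[CareEvent],
    window_days: tuple[int, int] = (1, 8),
) -> dict[str, list[tuple[CareEvent, int]]]:
    """Attach care events to procedures by animal and post-operative day.

    An event attaches to a procedure iff it belongs to the same animal and
    its day offset (event_date − surgery_date, in calendar days) lies in the
    closed interval ``window_days``.  Day 0 — the surgery day itself — is
    outside the default window (1, 8).  The same event attaches to every
    same-animal procedure whose window covers it.

    Returns a mapping with an entry for *every* procedure (possibly empty),
    each a list of ``(event, day_offset)`` sorted by (day_offset, kind,
    drug_name, note_text) so output is independent of input row order.
    """
    lo, hi = window_days
    if not (1 <= lo <= hi):
        raise ValueError(f"window_days must satisfy 1 <= lo <= hi, got {window_days}")

    by_animal: dict[str, list[CareEvent]] = {}
    for ev in events:
        by_animal.setdefault(ev.animal_id, []).append(ev)

    linked: dict[str, list[tuple[CareEvent, int]]] = {}
    for proc in procedures:
        attached = []
        for ev in by_animal.get(proc.animal_id, ()):
            offset = (ev.event_date - proc.surgery_date).days
            if lo <= offset <= hi:
                attached.append((ev, offset))
        attached.sort(
            key=lambda pair: (
                pair[1],
                pair[0].kind.value,
                pair[0].drug_name,
                pair[0].note_text,
            )
        )
        linked[proc.procedure_id] = attached
    return linked
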