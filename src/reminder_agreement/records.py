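"""Visit-level clinical record model and JSON-Lines round-trip I/O.

A :class:`PatientVisitRecord` is the snapshot of one patient's chart as it
stood on the day of an outpatient visit: coded problems, dated (and possibly
valued) laboratory results, active medication classes, exam dates, and
hospital discharge diagnoses.  This is the sole input both reminder engines
see, so the model is deliberately minimal: everything a rule can test lives
in the flat event list.

The on-disk format is JSON Lines, one visit object per line (see
``data/visit_record.schema.json`` for the published schema).  Dates are
ISO-8601 calendar dates; no rule needs time-of-day.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Iterable, List, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "ConceptCode",
    "ClinicalEvent",
    "PatientVisitRecord",
    "RecordParseError",
    "RecordValidationError",
    "EVENT_KINDS",
    "read_visit_records",
    "write_visit_records",
]

#: Recognised vocabulary systems.  Codes in any other system are preserved
#: verbatim on read and simply never match a concept set.
KNOWN_SYSTEMS = ("SNOMED", "LOINC", "MEDCLASS", "ICD9", "LOCAL")

EVENT_KINDS = ("problem", "lab", "medication", "exam", "discharge_dx")


class RecordParseError(ValueError):
    """A line of a visit-record file is not well-formed JSON."""


class RecordValidationError(ValueError):
    """A structurally valid record violates a model invariant."""


class ConceptCode(BaseModel):
    """A coded clinical concept: (vocabulary system, code, optional label).

    Equality and hashing use only ``(system, code)``, case-sensitively; the
    display text is an annotation and never participates in matching.
    """

    model_config = ConfigDict(frozen=True)

    system: str = Field(min_length=1)
    code: str = Field(min_length=1)
    display: Optional[str] = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConceptCode):
            return NotImplemented
        return (self.system, self.code) == (other.system, other.code)

    def __hash__(self) -> int:
        return hash((self.system, self.code))

    @property
    def key(self) -> tuple[str, str]:
        return (self.system, self.code)


class ClinicalEvent(BaseModel):
    """One dated fact in a patient's chart.

    ``kind`` distinguishes how the fact entered the record (problem list,
    lab feed, active medication list, documented exam, hospital discharge
    diagnosis).  Labs may carry a numeric ``value`` (HbA1c in %, otherwise a
    unitless flag); non-lab events normally carry none.  ``medication``
    events represent a drug class active at visit time, so their date may
    equal the visit date.
    """

    model_config = ConfigDict(frozen=True)

    kind: str
    concept: ConceptCode
    effective_date: datetime.date
    value: Optional[float] = None

    @model_validator(mode="after")
    def _check_kind(self) -> "ClinicalEvent":
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; expected one of {EVENT_KINDS}")
        return self


class PatientVisitRecord(BaseModel):
    """All chart data visible to the rule engines for one patient visit."""

    model_config = ConfigDict(frozen=True)

    visit_id: str = Field(min_length=1)
    patient_id: str = Field(min_length=1)
    visit_date: datetime.date
    events: tuple[ClinicalEvent, ...] = ()

    @model_validator(mode="after")
    def _check_event_dates(self) -> "PatientVisitRecord":
        for ev in self.events:
            if ev.effective_date > self.visit_date:
                raise ValueError(
                    f"event {ev.concept.system}:{ev.concept.code} dated "
                    f"{ev.effective_date} is after visit_date {self.visit_date}"
                )
        return self

    def events_of_kind(self, kind: str) -> tuple[ClinicalEvent, ...]:
        return tuple(ev for ev in self.events if ev.kind == kind)


def _hba1c_value_check(record: PatientVisitRecord) -> None:
    # HbA1c labs must carry a plausible percentage; the concept list comes
    # from the shipped fixture vocabulary (lazy import avoids a cycle).
    from .vocabulary import concept_set

    hba1c = concept_set("HBA1C_LAB")
    for ev in record.events:
        if ev.kind == "lab" and ev.concept in hba1c:
            if ev.value is None or not (0.0 < ev.value < 25.0):
                raise RecordValidationError(
                    f"visit {record.visit_id}: HbA1c lab "
                    f"{ev.concept.system}:{ev.concept.code} must carry a numeric "
                    f"value in (0, 25), got {ev.value!r}"
                )


def _event_to_json(ev: ClinicalEvent) -> dict:
    obj = {
        "kind": ev.kind,
        "system": ev.concept.system,
        "code": ev.concept.code,
        "date": ev.effective_date.isoformat(),
    }
    if ev.concept.display is not None:
        obj["display"] = ev.concept.display
    if ev.value is not None:
        obj["value"] = ev.value
    return obj


def _event_from_json(obj: dict) -> ClinicalEvent:
    return ClinicalEvent(
        kind=obj["kind"],
        concept=ConceptCode(
            system=obj["system"], code=obj["code"], display=obj.get("display")
        ),
        effective_date=datetime.date.fromisoformat(obj["date"]),
        value=obj.get("value"),
    )


def record_to_json(record: PatientVisitRecord) -> dict:
    return {
        "visit_id": record.visit_id,
        "patient_id": record.patient_id,
        "visit_date": record.visit_date.isoformat(),
        "events": [_event_to_json(ev) for ev in record.events],
    }


def record_from_json(obj: dict) -> PatientVisitRecord:
    if not isinstance(obj, dict):
        raise RecordValidationError(f"expected a JSON object, got {type(obj).__name__}")
    try:
        record = PatientVisitRecord(
            visit_id=obj.get("visit_id", ""),
            patient_id=obj.get("patient_id", ""),
            visit_date=datetime.date.fromisoformat(obj["visit_date"]),
            events=tuple(_event_from_json(e) for e in obj.get("events", [])),
        )
    except (ValidationError, ValueError, KeyError, TypeError) as exc:
        vid = obj.get("visit_id", "<unknown>")
        raise RecordValidationError(f"visit {vid}: {exc}") from exc
    _hba1c_value_check(record)
    return record


def read_visit_records(path: str | Path) -> List[PatientVisitRecord]:
    """Read a JSON-Lines cohort file, validating every record.

    Line order is preserved.  An empty file yields an empty list.  Raises
    :class:`RecordParseError` (naming the line number) for malformed JSON and
    :class:`RecordValidationError` (naming the visit) for invariant
    violations, including duplicated ``visit_id`` values within the file.
    """
    path = Path(path)
    records: List[PatientVisitRecord] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise RecordParseError(f"{path}: line {lineno}: {exc}") from exc
            record = record_from_json(obj)
            if record.visit_id in seen:
                raise RecordValidationError(
                    f"{path}: line {lineno}: duplicate visit_id {record.visit_id!r}"
                )
            seen.add(record.visit_id)
            records.append(record)
    return records


def write_visit_records(records: Iterable[PatientVisitRecord], path: str | Path) -> None:
    """Write records as JSON Lines (UTF-8, LF).  Round-trips with the reader."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for record in records:
            fh.write(json.dumps(record_to_json(record), ensure_ascii=False))
            fh.write("\n")
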