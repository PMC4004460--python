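"""Shared builders for constructing visit records in tests."""

from __future__ import annotations

import datetime
from typing import Optional

from reminder_agreement import ClinicalEvent, ConceptCode, PatientVisitRecord
from reminder_agreement.vocabulary import concept_set

VISIT_DATE = datetime.date(2011, 11, 15)


def code(set_name: str) -> ConceptCode:
    """First member (by code) of a named vocabulary set."""
    return sorted(concept_set(set_name).members, key=lambda c: (c.system, c.code))[0]


def ev(
    kind: str,
    set_name: Optional[str] = None,
    days_ago: int = 30,
    value: Optional[float] = None,
    concept: Optional[ConceptCode] = None,
    visit_date: datetime.date = VISIT_DATE,
) -> ClinicalEvent:
    return ClinicalEvent(
        kind=kind,
        concept=concept if concept is not None else code(set_name),
        effective_date=visit_date - datetime.timedelta(days=days_ago),
        value=value,
    )


def rec(*events: ClinicalEvent, visit_id: str = "V1", visit_date: datetime.date = VISIT_DATE) -> PatientVisitRecord:
    return PatientVisitRecord(
        visit_id=visit_id, patient_id="P1", visit_date=visit_date, events=tuple(events)
    )
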