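"""The 11 preventive-care reminder rules.

Each rule is a pure predicate over one :class:`PatientVisitRecord` under a
:class:`RuleProfile`; firing produces the rule's fixed display message.  The
set covers the diabetes quality bundle (HbA1c cadence, microalbumin
screening, ACE-I/ARB advice in renal disease, annual eye and foot exams),
an annual blood-pressure check, and antiplatelet advice in coronary artery
disease (CAD).

Month arithmetic
----------------
No clinical source defines "6 months" precisely, so elapsed time is
computed on day granularity as ``days / 30.4375`` (the mean Gregorian month
length), kept as an exact rational.  Interval phrases then follow fixed
half-open conventions: "within last N months" means elapsed < N, "over N
months ago" means elapsed > N, and "between A and B months ago" means
A <= elapsed < B.  With these conventions the three HbA1c rules partition
the timeline, which makes their pairwise mutual exclusion structural rather
than accidental.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from fractions import Fraction
from typing import List, Optional, Tuple

from .profiles import RuleProfile
from .records import ClinicalEvent, PatientVisitRecord
from .vocabulary import ConceptSet

__all__ = [
    "MONTH_DAYS",
    "REMINDER_IDS",
    "MESSAGES",
    "ReminderOutput",
    "months_before",
    "last_result",
    "is_diabetic",
    "has_cad",
    "evaluate_reminder",
    "evaluate_all",
]

#: Mean Gregorian month length in days (exactly 487/16 = 30.4375).
MONTH_DAYS = Fraction(487, 16)

REMINDER_IDS = tuple(range(1, 12))

MESSAGES = {
    1: (
        "Diabetic patient is overdue for HgbA1c measurement (recommended every 6 months)\n"
        "• Order HgbA1c now."
    ),
    2: (
        "Diabetic patient is almost due for HgbA1c measurement (recommended every 6 months)\n"
        "• Order HgbA1c now."
    ),
    3: (
        "Last HgbA1c was greater than 8% and over 3 months ago (recommended every 3 months "
        "in poorly controlled patient)\n"
        "• Order HgbA1c now."
    ),
    4: (
        "Diabetic patient is due for urine microalbumin/creatinine ratio measurement "
        "(recommended yearly)\n"
        "• Order malb/creat ratio now."
    ),
    5: (
        "Diabetic patient with renal disease, consider starting angiotensin-converting "
        "enzyme inhibitor (ACE-I).\n"
        "• Start ACE-I."
    ),
    6: (
        "Diabetic patient with renal disease, contraindications to ACE-I present, consider "
        "starting angiotensin-2 receptor antagonist (ARB).\n"
        "• Start ARB."
    ),
    7: (
        "Diabetic patient is due for ophthalmologic exam (recommended yearly)\n"
        "• Document the eye exam.\n"
        "• Refer to Ophthalmologist.\n"
        "• Refer to Optometrist."
    ),
    8: (
        "Diabetic patient is due for foot exam (recommended yearly)\n"
        "• Document the foot exam.\n"
        "• Refer to Podiatrist."
    ),
    9: (
        "Patient is overdue for blood pressure assessment (recommended yearly)\n"
        "• Document the blood pressure."
    ),
    10: (
        "Patient has CAD or equivalent, consider starting anti-platelet therapy, but "
        "potential contraindications exist.\n"
        "• Start aspirin.\n"
        "• Start clopidogrel."
    ),
    11: (
        "Patient has CAD or equivalent, recommend starting anti-platelet therapy.\n"
        "• Start aspirin.\n"
        "• Start clopidogrel."
    ),
}


@dataclass(frozen=True)
class ReminderOutput:
    """Fire/no-fire decision for one (visit, rule) pair."""

    visit_id: str
    reminder_id: int
    fired: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.fired != bool(self.message):
            raise ValueError("message must be non-empty iff fired")


def months_before(visit_date: datetime.date, event_date: datetime.date) -> Fraction:
    """Elapsed months between an event and the visit, as an exact rational.

    ``days / 30.4375`` on day granularity; raises ``ValueError`` if the event
    postdates the visit.
    """
    days = (visit_date - event_date).days
    if days < 0:
        raise ValueError(f"event date {event_date} is after visit date {visit_date}")
    return Fraction(days) / MONTH_DAYS


# -- record queries ---------------------------------------------------------


def last_result(
    record: PatientVisitRecord, lab_set: ConceptSet
) -> Optional[Tuple[Optional[float], datetime.date]]:
    """Latest lab in ``lab_set`` on/before the visit, or None.

    Same-date ties are broken toward the larger value (conservative toward
    alerting on a high HbA1c); a valued result outranks an unvalued one on
    the same date.
    """
    best: Optional[ClinicalEvent] = None
    for ev in record.events:
        if ev.kind != "lab" or ev.concept not in lab_set:
            continue
        if best is None:
            best = ev
            continue
        key = (ev.effective_date, ev.value if ev.value is not None else float("-inf"))
        best_key = (best.effective_date, best.value if best.value is not None else float("-inf"))
        if key > best_key:
            best = ev
    if best is None:
        return None
    return (best.value, best.effective_date)


def _has_event(record: PatientVisitRecord, kind: str, cs: ConceptSet) -> bool:
    return any(ev.kind == kind and ev.concept in cs for ev in record.events)


def _has_event_within(
    record: PatientVisitRecord, kind: str, cs: ConceptSet, months: Fraction | int
) -> bool:
    return any(
        ev.kind == kind
        and ev.concept in cs
        and months_before(record.visit_date, ev.effective_date) < months
        for ev in record.events
    )


def _last_event_date(
    record: PatientVisitRecord, kind: str, cs: ConceptSet
) -> Optional[datetime.date]:
    dates = [ev.effective_date for ev in record.events if ev.kind == kind and ev.concept in cs]
    return max(dates) if dates else None


def _on_medication(record: PatientVisitRecord, profile: RuleProfile, role: str) -> bool:
    return _has_event(record, "medication", profile.role(role))


# -- guard predicates -------------------------------------------------------


def is_diabetic(record: PatientVisitRecord, profile: RuleProfile) -> bool:
    """Does this profile consider the patient diabetic?

    Sources are configurable: the problem list (optionally discounting
    patients whose only diabetes codes are gestational), active hypoglycemic
    medications (oral agents or insulin), and ICD9 hospital discharge
    diagnoses.
    """
    if "problem_list" in profile.diabetes_sources:
        dm = profile.role("DIABETES")
        gdm = profile.role("GESTATIONAL_DIABETES")
        matches = [ev.concept for ev in record.events if ev.kind == "problem" and ev.concept in dm]
        if matches:
            if profile.exclude_gestational_diabetes and all(c in gdm for c in matches):
                pass  # gestational-only history does not count
            else:
                return True
    if "hypoglycemic_meds" in profile.diabetes_sources:
        if _on_medication(record, profile, "ORAL_HYPOGLYCEMIC") or _on_medication(
            record, profile, "INSULIN"
        ):
            return True
    if "icd9_discharge" in profile.diabetes_sources:
        if _has_event(record, "discharge_dx", profile.role("DIABETES_ICD9")):
            return True
    return False


def has_cad(record: PatientVisitRecord, profile: RuleProfile) -> bool:
    """CAD on the problem list, or angina if the profile equates the two."""
    if _has_event(record, "problem", profile.role("CAD")):
        return True
    return profile.angina_implies_cad and _has_event(record, "problem", profile.role("ANGINA"))


def _has_renal_disease(record: PatientVisitRecord, profile: RuleProfile) -> bool:
    return _has_event(record, "problem", profile.role("RENAL_DISEASE"))


def _microalbumin_evidence(record: PatientVisitRecord, profile: RuleProfile) -> bool:
    # Evidence window for the ACE-I/ARB rules; None means no time bound.
    cs = profile.role("MICROALBUMIN_LAB")
    lookback = profile.ace_evidence_lookback_months
    if lookback is None:
        return _has_event(record, "lab", cs)
    return _has_event_within(record, "lab", cs, lookback)


def _ace_arb_common_guard(record: PatientVisitRecord, profile: RuleProfile) -> bool:
    return (
        is_diabetic(record, profile)
        and _has_renal_disease(record, profile)
        and not _has_event(record, "problem", profile.role("ESRD"))
        and not _on_medication(record, profile, "ACE_I")
        and not _on_medication(record, profile, "ARB")
        and _microalbumin_evidence(record, profile)
    )


# -- individual rules -------------------------------------------------------


def _rule_1(record: PatientVisitRecord, profile: RuleProfile) -> bool:
    if not is_diabetic(record, profile):
        return False
    last = last_result(record, profile.role("HBA1C_LAB"))
    if last is None:
        return True
    return months_before(record.visit_date, last[1]) >= profile.windows.hba1c_due


def _rule_2(record: PatientVisitRecord, profile: RuleProfile) -> bool:
    if not is_diabetic(record, profile):
        return False
    last = last_result(record, profile.role("HBA1C_LAB"))
    if last is None:
        return False
    elapsed = months_before(record.visit_date, last[1])
    w = profile.windows
    return w.hba1c_almost_due_lo <= elapsed < w.hba1c_due


def _rule_3(record: PatientVisitRecord, profile: RuleProfile) -> bool:
    if not is_diabetic(record, profile):
        return False
    last = last_result(record, profile.role("HBA1C_LAB"))
    if last is None or last[0] is None:
        return False
    elapsed = months_before(record.visit_date, last[1])
    w = profile.windows
    return w.hba1c_poor_lo <= elapsed < w.hba1c_poor_hi and last[0] > w.hba1c_poor_threshold


def _rule_4(record: PatientVisitRecord, profile: RuleProfile) -> bool:
    if not is_diabetic(record, profile):
        return False
    if profile.microalbumin_excludes_renal_disease and _has_renal_disease(record, profile):
        return False
    return not _has_event_within(
        record, "lab", profile.role("MICROALBUMIN_LAB"), profile.windows.microalbumin_lookback
    )


def _rule_5(record: PatientVisitRecord, profile: RuleProfile) -> bool:
    return _ace_arb_common_guard(record, profile) and not _has_event(
        record, "problem", profile.role("ACE_CONTRA")
    )


def _rule_6(record: PatientVisitRecord, profile: RuleProfile) -> bool:
    return (
        _ace_arb_common_guard(record, profile)
        and _has_event(record, "problem", profile.role("ACE_CONTRA"))
        and not _has_event(record, "problem", profile.role("ARB_CONTRA"))
    )


def _rule_7(record: PatientVisitRecord, profile: RuleProfile) -> bool:
    if not is_diabetic(record, profile):
        return False
    if "blindness" in profile.eye_exam_exclusions and _has_event(
        record, "problem", profile.role("BLINDNESS")
    ):
        return False
    if "eye_clinic_visit_within_12mo" in profile.eye_exam_exclusions and _has_event_within(
        record, "exam", profile.role("EYE_CLINIC_VISIT"), 12
    ):
        return False
    last = _last_event_date(record, "exam", profile.role("EYE_EXAM"))
    if last is None:
        return True
    return months_before(record.visit_date, last) > profile.windows.eye_exam_lookback


def _rule_8(record: PatientVisitRecord, profile: RuleProfile) -> bool:
    if not is_diabetic(record, profile):
        return False
    last = _last_event_date(record, "exam", profile.role("FOOT_EXAM"))
    if last is None:
        return True
    return months_before(record.visit_date, last) > profile.windows.foot_exam_lookback


def _rule_9(record: PatientVisitRecord, profile: RuleProfile) -> bool:
    return not _has_event_within(
        record, "lab", profile.role("BP_LAB"), profile.windows.bp_lookback
    )


def _antiplatelet_common_guard(record: PatientVisitRecord, profile: RuleProfile) -> bool:
    return has_cad(record, profile) and not _on_medication(record, profile, "ANTIPLATELET")


def _rule_10(record: PatientVisitRecord, profile: RuleProfile) -> bool:
    return _antiplatelet_common_guard(record, profile) and _has_event(
        record, "problem", profile.role("ANTIPLATELET_CONTRA")
    )


def _rule_11(record: PatientVisitRecord, profile: RuleProfile) -> bool:
    return _antiplatelet_common_guard(record, profile) and not _has_event(
        record, "problem", profile.role("ANTIPLATELET_CONTRA")
    )


_RULES = {
    1: _rule_1,
    2: _rule_2,
    3: _rule_3,
    4: _rule_4,
    5: _rule_5,
    6: _rule_6,
    7: _rule_7,
    8: _rule_8,
    9: _rule_9,
    10: _rule_10,
    11: _rule_11,
}


def evaluate_reminder(
    record: PatientVisitRecord, profile: RuleProfile, reminder_id: int
) -> ReminderOutput:
    """Evaluate one rule; pure, and deterministic for a given (record, profile)."""
    try:
        rule = _RULES[reminder_id]
    except KeyError:
        raise ValueError(f"reminder_id must be in 1..11, got {reminder_id!r}") from None
    fired = rule(record, profile)
    return ReminderOutput(
        visit_id=record.visit_id,
        reminder_id=reminder_id,
        fired=fired,
        message=MESSAGES[reminder_id] if fired else "",
    )


def evaluate_all(record: PatientVisitRecord, profile: RuleProfile) -> List[ReminderOutput]:
    """Evaluate all 11 rules, ordered by reminder id."""
    return [evaluate_reminder(record, profile, rid) for rid in REMINDER_IDS]
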