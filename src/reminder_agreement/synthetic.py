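"""Synthetic visit cohorts with tunable engine-discordance structure.

The generator emulates the statistical shape a reminder-agreement study
assumes: a primary-care cohort (default 405 visits over a three-month
window) containing diabetes, CAD and renal-disease subpopulations, labs and
exams with recency spread around the rules' 3/5/6/11/12-month boundaries,
and explicit "discordance knobs" — coding and charting patterns on which a
consortium-style (CLOUD) and a locally-maintained (LOCAL) rule profile
disagree:

* ``p_bp_sitting_code`` — blood pressure stored under the sitting-systolic
  LOINC code that only the broad profile recognises (terminology);
* ``p_gestational_only``, ``p_hypoglycemic_med_without_problem``,
  ``p_angina_without_cad`` — diabetes/CAD asserted by evidence only one
  profile accepts (local practice variation);
* ``p_renal`` — a renal subpopulation, which exposes both the
  microalbuminuria-evidence lookback difference and the renal exclusion on
  the screening rule (temporal windows / exclusions);
* ``p_ace_contra``, ``p_antiplatelet_contra_extended_only``,
  ``p_blindness``, ``p_eye_clinic_visit`` — exclusion codes only one
  profile's contraindication/exclusion sets contain.

With every knob at zero the two built-in profiles are behaviourally
indistinguishable on the generated records, which gives the pipeline an
exact null to test against.  Default parameter values live in
``data/default_cohort_config.json``; they are stand-ins chosen to put the
per-rule firing prevalences in a realistic primary-care range, not a claim
about any real cohort.  One visit per synthetic patient; no within-patient
correlation is modelled.
"""

from __future__ import annotations

import datetime
import json
from importlib import resources
from typing import Dict, FrozenSet, List

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .records import ClinicalEvent, ConceptCode, PatientVisitRecord
from .rules import MONTH_DAYS
from .vocabulary import concept_set

__all__ = [
    "SyntheticCohortConfig",
    "DISCORDANCE_KNOBS",
    "DISCREPANCY_CLASSES",
    "CLASS_RULE_SUBSETS",
    "concordant_config",
    "generate_cohort",
    "concordance_stress_cohort",
]

_DEFAULTS: dict = json.loads(
    resources.files("reminder_agreement.data")
    .joinpath("default_cohort_config.json")
    .read_text("utf-8")
)

#: Config fields that create CLOUD-vs-LOCAL disagreement when non-zero.
DISCORDANCE_KNOBS = (
    "p_gestational_only",
    "p_angina_without_cad",
    "p_hypoglycemic_med_without_problem",
    "p_bp_sitting_code",
    "p_renal",
    "p_ace_contra",
    "p_antiplatelet_contra_extended_only",
    "p_blindness",
    "p_eye_clinic_visit",
)

#: Knob ceilings activated per discrepancy class (scaled by intensity).
DISCREPANCY_CLASSES: Dict[str, Dict[str, float]] = {
    "terminology": {"p_bp_sitting_code": 1.0},
    "practice_variation": {
        "p_gestational_only": 0.10,
        "p_hypoglycemic_med_without_problem": 0.15,
        "p_angina_without_cad": 0.08,
    },
    "temporal": {"p_renal": 0.25},
    "exclusions": {
        "p_renal": 0.25,
        "p_ace_contra": 0.30,
        "p_blindness": 0.10,
        "p_eye_clinic_visit": 0.20,
        "p_antiplatelet_contra_extended_only": 0.15,
    },
}

#: Rules each discrepancy class can perturb (all others must stay concordant).
#: The renal prerequisite used by the temporal class also arms the
#: renal-disease exclusion on the screening rule, so rule 4 belongs to both
#: the temporal and exclusions subsets.
CLASS_RULE_SUBSETS: Dict[str, FrozenSet[int]] = {
    "terminology": frozenset({9}),
    "practice_variation": frozenset({1, 2, 3, 4, 5, 6, 7, 8, 10, 11}),
    "temporal": frozenset({4, 5, 6}),
    "exclusions": frozenset({4, 5, 6, 7, 10, 11}),
}

_PROB_FIELDS = (
    "p_diabetes",
    "p_gestational_only",
    "p_cad",
    "p_angina_without_cad",
    "p_renal",
    "p_esrd_given_renal",
    "p_on_ace",
    "p_on_arb",
    "p_on_antiplatelet",
    "p_hypoglycemic_med_without_problem",
    "p_hba1c",
    "p_microalbumin",
    "p_bp",
    "p_eye_exam",
    "p_foot_exam",
    "p_bp_sitting_code",
    "p_ace_contra",
    "p_antiplatelet_contra_core",
    "p_antiplatelet_contra_extended_only",
    "p_blindness",
    "p_eye_clinic_visit",
)


class SyntheticCohortConfig(BaseModel):
    """All parameters of the cohort generator; defaults from the packaged config file."""

    model_config = ConfigDict(frozen=True)

    n_visits: int = Field(_DEFAULTS["n_visits"], ge=1)
    seed: int = _DEFAULTS["seed"]

    p_diabetes: float = _DEFAULTS["p_diabetes"]
    p_gestational_only: float = _DEFAULTS["p_gestational_only"]
    p_cad: float = _DEFAULTS["p_cad"]
    p_angina_without_cad: float = _DEFAULTS["p_angina_without_cad"]
    p_renal: float = _DEFAULTS["p_renal"]
    p_esrd_given_renal: float = _DEFAULTS["p_esrd_given_renal"]

    p_on_ace: float = _DEFAULTS["p_on_ace"]
    p_on_arb: float = _DEFAULTS["p_on_arb"]
    p_on_antiplatelet: float = _DEFAULTS["p_on_antiplatelet"]
    p_hypoglycemic_med_without_problem: float = _DEFAULTS["p_hypoglycemic_med_without_problem"]

    # per-lab/exam presence probabilities; recency uniform on [0, max] months
    p_hba1c: float = _DEFAULTS["p_hba1c"]
    p_microalbumin: float = _DEFAULTS["p_microalbumin"]
    p_bp: float = _DEFAULTS["p_bp"]
    p_eye_exam: float = _DEFAULTS["p_eye_exam"]
    p_foot_exam: float = _DEFAULTS["p_foot_exam"]
    lab_recency_max_months: float = Field(_DEFAULTS["lab_recency_max_months"], gt=0)

    hba1c_mean: float = _DEFAULTS["hba1c_mean"]
    hba1c_sd: float = Field(_DEFAULTS["hba1c_sd"], gt=0)

    p_bp_sitting_code: float = _DEFAULTS["p_bp_sitting_code"]
    p_ace_contra: float = _DEFAULTS["p_ace_contra"]
    p_antiplatelet_contra_core: float = _DEFAULTS["p_antiplatelet_contra_core"]
    p_antiplatelet_contra_extended_only: float = _DEFAULTS["p_antiplatelet_contra_extended_only"]
    p_blindness: float = _DEFAULTS["p_blindness"]
    p_eye_clinic_visit: float = _DEFAULTS["p_eye_clinic_visit"]

    @model_validator(mode="after")
    def _check_probabilities(self) -> "SyntheticCohortConfig":
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.p_diabetes + self.p_gestational_only > 1.0:
            raise ValueError("p_diabetes + p_gestational_only must not exceed 1")
        if self.p_cad + self.p_angina_without_cad > 1.0:
            raise ValueError("p_cad + p_angina_without_cad must not exceed 1")
        return self


def concordant_config(n_visits: int = 405, seed: int = 0, **overrides) -> SyntheticCohortConfig:
    """Default config with every discordance knob set to zero."""
    zeroed = {k: 0.0 for k in DISCORDANCE_KNOBS}
    zeroed.update(overrides)
    return SyntheticCohortConfig(n_visits=n_visits, seed=seed, **zeroed)


_BASE_DATE = datetime.date(2011, 10, 1)  # start of a 92-day visit window


def _months_ago(visit_date: datetime.date, months: float) -> datetime.date:
    return visit_date - datetime.timedelta(days=int(round(months * float(MONTH_DAYS))))


def _one(name: str) -> ConceptCode:
    """Any single member of a vocabulary set (sets used singly here)."""
    return next(iter(concept_set(name).members))


def _pick(rng: np.random.Generator, name: str) -> ConceptCode:
    members = sorted(concept_set(name).members, key=lambda c: (c.system, c.code))
    return members[int(rng.integers(len(members)))]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    while True:
        v = rng.normal(mean, sd)
        if lo < v < hi:
            return float(v)


def generate_cohort(config: SyntheticCohortConfig) -> List[PatientVisitRecord]:
    """Generate ``config.n_visits`` valid records, deterministically from the seed."""
    rng = np.random.default_rng(config.seed)
    records: List[PatientVisitRecord] = []

    for i in range(config.n_visits):
        visit_date = _BASE_DATE + datetime.timedelta(days=int(rng.integers(0, 92)))
        events: List[ClinicalEvent] = []

        def problem(code: ConceptCode, months_back: float) -> None:
            events.append(
                ClinicalEvent(
                    kind="problem",
                    concept=code,
                    effective_date=_months_ago(visit_date, months_back),
                )
            )

        def medication(set_name: str) -> None:
            events.append(
                ClinicalEvent(
                    kind="medication", concept=_one(set_name), effective_date=visit_date
                )
            )

        def lab(code: ConceptCode, months_back: float, value: float | None = None) -> None:
            events.append(
                ClinicalEvent(
                    kind="lab",
                    concept=code,
                    effective_date=_months_ago(visit_date, months_back),
                    value=value,
                )
            )

        def history_months() -> float:
            return float(rng.uniform(1.0, 60.0))

        # diabetes status: problem-list, gestational-only, or neither
        u = rng.random()
        gdm_only = u < config.p_gestational_only
        dm_problem = (not gdm_only) and u < config.p_gestational_only + config.p_diabetes
        if gdm_only:
            problem(_one("GESTATIONAL_DIABETES"), history_months())
        elif dm_problem:
            problem(_pick(rng, "DIABETES"), history_months())
            if rng.random() < 0.5:  # charted treatment alongside the problem
                medication("ORAL_HYPOGLYCEMIC")
        elif rng.random() < config.p_hypoglycemic_med_without_problem:
            # diabetes evidence only the broad-source profile accepts
            if rng.random() < 0.5:
                medication("ORAL_HYPOGLYCEMIC" if rng.random() < 0.7 else "INSULIN")
            else:
                events.append(
                    ClinicalEvent(
                        kind="discharge_dx",
                        concept=_pick(rng, "DIABETES_ICD9"),
                        effective_date=_months_ago(visit_date, float(rng.uniform(1.0, 24.0))),
                    )
                )

        # coronary disease: CAD problem, or angina coded without CAD
        v = rng.random()
        if v < config.p_angina_without_cad:
            problem(_one("ANGINA"), history_months())
        elif v < config.p_angina_without_cad + config.p_cad:
            problem(_pick(rng, "CAD"), history_months())

        # renal disease and ESRD
        if rng.random() < config.p_renal:
            problem(_pick(rng, "RENAL_DISEASE"), history_months())
            if rng.random() < config.p_esrd_given_renal:
                problem(_one("ESRD"), history_months())

        # active medication classes
        if rng.random() < config.p_on_ace:
            medication("ACE_I")
        if rng.random() < config.p_on_arb:
            medication("ARB")
        if rng.random() < config.p_on_antiplatelet:
            medication("ANTIPLATELET")

        # contraindications and exclusion conditions
        if rng.random() < config.p_ace_contra:
            code = [_one("ACE_ALLERGY"), _one("PREGNANCY"), _one("HYPERKALEMIA")][
                int(rng.integers(3))
            ]
            problem(code, float(rng.uniform(0.0, 12.0)))
        if rng.random() < config.p_antiplatelet_contra_core:
            code = [_one("BLEEDING_DISORDER"), _one("THROMBOCYTOPENIA"), _one("GI_BLEED")][
                int(rng.integers(3))
            ]
            problem(code, history_months())
        if rng.random() < config.p_antiplatelet_contra_extended_only:
            code = [
                _one("ESOPHAGEAL_VARICES"),
                _one("COAG_FACTOR_DEFICIENCY"),
                _one("CEREBRAL_HEMORRHAGE"),
            ][int(rng.integers(3))]
            problem(code, history_months())
        if rng.random() < config.p_blindness:
            problem(_one("BLINDNESS"), history_months())
        if rng.random() < config.p_eye_clinic_visit:
            # sampled inside the 12-month exclusion window so the knob binds
            events.append(
                ClinicalEvent(
                    kind="exam",
                    concept=_one("EYE_CLINIC_VISIT"),
                    effective_date=_months_ago(visit_date, float(rng.uniform(0.0, 12.0))),
                )
            )

        # labs and exams, recency uniform over [0, max] months
        recency_max = config.lab_recency_max_months
        if rng.random() < config.p_hba1c:
            lab(
                _one("HBA1C_LAB"),
                float(rng.uniform(0.0, recency_max)),
                _truncated_normal(rng, config.hba1c_mean, config.hba1c_sd, 4.0, 15.0),
            )
        if rng.random() < config.p_microalbumin:
            lab(_one("MICROALBUMIN_LAB"), float(rng.uniform(0.0, recency_max)))
        if rng.random() < config.p_bp:
            sitting = rng.random() < config.p_bp_sitting_code
            lab(
                _one("BP_SYSTOLIC_SITTING") if sitting else _one("BP_SYSTOLIC"),
                float(rng.uniform(0.0, recency_max)),
            )
        for present_p, set_name in (
            (config.p_eye_exam, "EYE_EXAM"),
            (config.p_foot_exam, "FOOT_EXAM"),
        ):
            if rng.random() < present_p:
                events.append(
                    ClinicalEvent(
                        kind="exam",
                        concept=_one(set_name),
                        effective_date=_months_ago(
                            visit_date, float(rng.uniform(0.0, recency_max))
                        ),
                    )
                )

        records.append(
            PatientVisitRecord(
                visit_id=f"V{i:05d}",
                patient_id=f"P{i:05d}",
                visit_date=visit_date,
                events=tuple(events),
            )
        )
    return records


def concordance_stress_cohort(
    discrepancy_class: str, intensity: float, n: int = 405, seed: int = 0
) -> List[PatientVisitRecord]:
    """Cohort in which only one discrepancy class's knobs are active.

    ``intensity`` in [0, 1] scales the class's knob ceilings; at 0 the
    cohort is fully concordant between the built-in profiles.
    """
    if discrepancy_class not in DISCREPANCY_CLASSES:
        raise ValueError(
            f"unknown discrepancy class {discrepancy_class!r}; "
            f"expected one of {sorted(DISCREPANCY_CLASSES)}"
        )
    if not 0.0 <= intensity <= 1.0:
        raise ValueError(f"intensity must lie in [0, 1], got {intensity}")
    knobs = {
        name: ceiling * intensity
        for name, ceiling in DISCREPANCY_CLASSES[discrepancy_class].items()
    }
    return generate_cohort(concordant_config(n_visits=n, seed=seed, **knobs))
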