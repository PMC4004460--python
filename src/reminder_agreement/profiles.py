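"""Rule profiles: named parameterizations of the 11 preventive-care rules.

Two engines can encode "the same" guideline and still disagree visit by
visit, through four mechanisms: terminology misalignment (which codes a
concept set recognises), local practice variation (what counts as diabetes
or CAD), temporal windows (how far back evidence is sought), and use of
exclusions (which patients a reminder is suppressed for).  A
:class:`RuleProfile` makes every one of those choices an explicit parameter,
and the two built-in profiles — ``CLOUD`` (consortium-style) and ``LOCAL``
(home-grown-style) — instantiate the two ends observed in practice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import FrozenSet, Mapping, Optional

from .vocabulary import ConceptSet, concept_set, union

__all__ = [
    "RuleWindows",
    "RuleProfile",
    "PROFILE_ROLES",
    "cloud_profile",
    "local_profile",
    "load_profile",
]

#: Concept-set roles every profile must bind.
PROFILE_ROLES = (
    "DIABETES",
    "GESTATIONAL_DIABETES",
    "DIABETES_ICD9",
    "RENAL_DISEASE",
    "ESRD",
    "CAD",
    "ANGINA",
    "HBA1C_LAB",
    "MICROALBUMIN_LAB",
    "BP_LAB",
    "EYE_EXAM",
    "FOOT_EXAM",
    "BLINDNESS",
    "EYE_CLINIC_VISIT",
    "ACE_I",
    "ARB",
    "ANTIPLATELET",
    "ORAL_HYPOGLYCEMIC",
    "INSULIN",
    "ACE_CONTRA",
    "ARB_CONTRA",
    "ANTIPLATELET_CONTRA",
)

DIABETES_SOURCES = frozenset({"problem_list", "hypoglycemic_meds", "icd9_discharge"})
EYE_EXAM_EXCLUSIONS = frozenset({"blindness", "eye_clinic_visit_within_12mo"})


@dataclass(frozen=True)
class RuleWindows:
    """Temporal parameters of the rules, in elapsed months (HbA1c threshold in %).

    The HbA1c cascade uses half-open intervals on elapsed time: "due" means
    no result closer than ``hba1c_due`` months, "almost due" means the last
    result lies in [``hba1c_almost_due_lo``, ``hba1c_due``), and "poorly
    controlled" means the last result lies in [``hba1c_poor_lo``,
    ``hba1c_poor_hi``) with a value strictly above ``hba1c_poor_threshold``.
    """

    hba1c_due: int = 6
    hba1c_almost_due_lo: int = 5
    hba1c_poor_lo: int = 3
    hba1c_poor_hi: int = 5
    hba1c_poor_threshold: float = 8.0
    microalbumin_lookback: int = 11
    eye_exam_lookback: int = 11
    foot_exam_lookback: int = 11
    bp_lookback: int = 12

    def __post_init__(self) -> None:
        if not self.hba1c_almost_due_lo < self.hba1c_due:
            raise ValueError("hba1c_almost_due_lo must be < hba1c_due")
        if not self.hba1c_poor_lo < self.hba1c_poor_hi:
            raise ValueError("hba1c_poor_lo must be < hba1c_poor_hi")
        for name in (
            "hba1c_due",
            "hba1c_almost_due_lo",
            "hba1c_poor_lo",
            "hba1c_poor_hi",
            "microalbumin_lookback",
            "eye_exam_lookback",
            "foot_exam_lookback",
            "bp_lookback",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"window {name} must be positive")


@dataclass(frozen=True)
class RuleProfile:
    """Complete parameterization of the 11-rule set for one engine."""

    name: str
    concept_sets: Mapping[str, ConceptSet]
    diabetes_sources: FrozenSet[str]
    exclude_gestational_diabetes: bool
    angina_implies_cad: bool
    microalbumin_excludes_renal_disease: bool
    #: months of lookback for microalbuminuria evidence in the ACE/ARB rules;
    #: None means unbounded (any result on record counts).
    ace_evidence_lookback_months: Optional[int]
    eye_exam_exclusions: FrozenSet[str]
    windows: RuleWindows = field(default_factory=RuleWindows)

    def __post_init__(self) -> None:
        missing = [r for r in PROFILE_ROLES if r not in self.concept_sets]
        if missing:
            raise ValueError(f"profile {self.name!r} missing concept-set roles: {missing}")
        bad = self.diabetes_sources - DIABETES_SOURCES
        if bad:
            raise ValueError(f"unknown diabetes sources: {sorted(bad)}")
        bad = self.eye_exam_exclusions - EYE_EXAM_EXCLUSIONS
        if bad:
            raise ValueError(f"unknown eye-exam exclusions: {sorted(bad)}")
        if self.ace_evidence_lookback_months is not None and self.ace_evidence_lookback_months <= 0:
            raise ValueError("ace_evidence_lookback_months must be positive or None")

    def role(self, name: str) -> ConceptSet:
        return self.concept_sets[name]

    def equivalent_to(self, other: "RuleProfile") -> bool:
        """True when every behavioural parameter matches (names may differ)."""
        return (
            {r: self.role(r).members for r in PROFILE_ROLES}
            == {r: other.role(r).members for r in PROFILE_ROLES}
            and self.diabetes_sources == other.diabetes_sources
            and self.exclude_gestational_diabetes == other.exclude_gestational_diabetes
            and self.angina_implies_cad == other.angina_implies_cad
            and self.microalbumin_excludes_renal_disease == other.microalbumin_excludes_renal_disease
            and self.ace_evidence_lookback_months == other.ace_evidence_lookback_months
            and self.eye_exam_exclusions == other.eye_exam_exclusions
            and self.windows == other.windows
        )


def _profile_from_dict(spec: dict) -> RuleProfile:
    sets = {
        role: union(role, (concept_set(n) for n in names))
        for role, names in spec["concept_sets"].items()
    }
    return RuleProfile(
        name=spec["name"],
        concept_sets=sets,
        diabetes_sources=frozenset(spec["diabetes_sources"]),
        exclude_gestational_diabetes=spec["exclude_gestational_diabetes"],
        angina_implies_cad=spec["angina_implies_cad"],
        microalbumin_excludes_renal_disease=spec["microalbumin_excludes_renal_disease"],
        ace_evidence_lookback_months=spec["ace_evidence_lookback_months"],
        eye_exam_exclusions=frozenset(spec["eye_exam_exclusions"]),
        windows=RuleWindows(**spec.get("windows", {})),
    )


@lru_cache(maxsize=8)
def _builtin(name: str) -> RuleProfile:
    text = resources.files("reminder_agreement.data").joinpath(f"{name}_profile.json").read_text("utf-8")
    return _profile_from_dict(json.loads(text))


def cloud_profile() -> RuleProfile:
    """The consortium-style profile (first engine of the comparison)."""
    return _builtin("cloud")


def local_profile() -> RuleProfile:
    """The locally-maintained-style profile (second engine of the comparison)."""
    return _builtin("local")


def load_profile(name_or_path: str | Path) -> RuleProfile:
    """Load a profile by built-in name (``cloud``/``local``) or JSON file path."""
    key = str(name_or_path).lower()
    if key in ("cloud", "local"):
        return _builtin(key)
    with open(name_or_path, "r", encoding="utf-8") as fh:
        return _profile_from_dict(json.load(fh))
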