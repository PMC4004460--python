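"""Rule-engine behaviour: month arithmetic, guards, the 11 rules, profiles."""

import dataclasses
import datetime
from fractions import Fraction

import pytest

from helpers import VISIT_DATE, code, ev, rec
from reminder_agreement import (
    MESSAGES,
    SyntheticCohortConfig,
    evaluate_all,
    evaluate_reminder,
    generate_cohort,
    has_cad,
    is_diabetic,
    last_result,
    months_before,
)
from reminder_agreement.vocabulary import concept_set


def days_ago(n: int) -> datetime.date:
    return VISIT_DATE - datetime.timedelta(days=n)


class TestMonthsBefore:
    def test_same_day_is_zero(self):
        assert months_before(VISIT_DATE, VISIT_DATE) == 0

    def test_183_days_is_just_over_six_months(self):
        m = months_before(VISIT_DATE, days_ago(183))
        assert m == Fraction(183 * 16, 487)
        assert m > 6

    def test_182_days_is_under_six_months(self):
        assert months_before(VISIT_DATE, days_ago(182)) < 6

    def test_152_days_is_under_five_months(self):
        m = months_before(VISIT_DATE, days_ago(152))
        assert 4 < m < 5

    def test_event_after_visit_rejected(self):
        with pytest.raises(ValueError):
            months_before(VISIT_DATE, VISIT_DATE + datetime.timedelta(days=1))


class TestLastResult:
    def test_no_matching_labs_absent(self, cloud):
        assert last_result(rec(), cloud.role("HBA1C_LAB")) is None

    def test_latest_date_wins(self, cloud):
        r = rec(
            ev("lab", "HBA1C_LAB", days_ago=100, value=7.1),
            ev("lab", "HBA1C_LAB", days_ago=10, value=6.5),
        )
        assert last_result(r, cloud.role("HBA1C_LAB")) == (6.5, days_ago(10))

    def test_same_date_tie_breaks_to_larger_value(self, cloud):
        r = rec(
            ev("lab", "HBA1C_LAB", days_ago=10, value=7.1),
            ev("lab", "HBA1C_LAB", days_ago=10, value=9.0),
        )
        assert last_result(r, cloud.role("HBA1C_LAB"))[0] == 9.0


class TestDiabetesGuard:
    def test_gestational_only_excluded_by_cloud_not_local(self, cloud, local):
        r = rec(ev("problem", "GESTATIONAL_DIABETES", days_ago=400))
        assert not is_diabetic(r, cloud)
        assert is_diabetic(r, local)

    def test_gestational_plus_regular_diabetes_counts_everywhere(self, cloud, local):
        r = rec(
            ev("problem", "GESTATIONAL_DIABETES", days_ago=400),
            ev("problem", "DIABETES", days_ago=200),
        )
        assert is_diabetic(r, cloud) and is_diabetic(r, local)

    def test_insulin_without_problem_only_counts_for_broad_sources(self, cloud, local):
        r = rec(ev("medication", "INSULIN", days_ago=0))
        assert not is_diabetic(r, cloud)
        assert is_diabetic(r, local)

    def test_icd9_discharge_only_counts_for_broad_sources(self, cloud, local):
        r = rec(ev("discharge_dx", "DIABETES_ICD9", days_ago=300))
        assert not is_diabetic(r, cloud)
        assert is_diabetic(r, local)


class TestCadGuard:
    def test_angina_counts_as_cad_only_when_profile_says_so(self, cloud, local):
        r = rec(ev("problem", "ANGINA", days_ago=60))
        assert r.events[0].concept.code == "194828000"
        assert has_cad(r, cloud)
        assert not has_cad(r, local)

    def test_empty_problem_list_is_not_cad(self, cloud, local):
        assert not has_cad(rec(), cloud) and not has_cad(rec(), local)


class TestHba1cCascade:
    def test_diabetic_with_no_result_is_overdue(self, cloud, local):
        r = rec(ev("problem", "DIABETES"))
        for profile in (cloud, local):
            out = evaluate_reminder(r, profile, 1)
            assert out.fired and out.message == MESSAGES[1]

    def test_six_month_boundary_183_vs_182_days(self, cloud):
        dm = ev("problem", "DIABETES", days_ago=700)
        just_over = rec(dm, ev("lab", "HBA1C_LAB", days_ago=183, value=7.0))
        just_under = rec(dm, ev("lab", "HBA1C_LAB", days_ago=182, value=7.0))
        assert evaluate_reminder(just_over, cloud, 1).fired
        assert not evaluate_reminder(just_under, cloud, 1).fired
        # 182 days is inside [5, 6) months: the almost-due rule takes over
        assert evaluate_reminder(just_under, cloud, 2).fired

    def test_poor_control_needs_value_strictly_above_threshold(self, cloud):
        dm = ev("problem", "DIABETES", days_ago=700)
        at_threshold = rec(dm, ev("lab", "HBA1C_LAB", days_ago=120, value=8.0))
        above = rec(dm, ev("lab", "HBA1C_LAB", days_ago=120, value=8.1))
        assert not evaluate_reminder(at_threshold, cloud, 3).fired
        assert evaluate_reminder(above, cloud, 3).fired


class TestMicroalbuminAndAceRules:
    def test_renal_exclusion_splits_the_profiles(self, cloud, local):
        r = rec(ev("problem", "DIABETES"), ev("problem", "RENAL_DISEASE"))
        assert not evaluate_reminder(r, cloud, 4).fired  # renal disease excluded
        assert evaluate_reminder(r, local, 4).fired

    def test_recent_microalbumin_satisfies_both(self, cloud, local):
        r = rec(
            ev("problem", "DIABETES"),
            ev("lab", "MICROALBUMIN_LAB", days_ago=60),
        )
        assert not evaluate_reminder(r, cloud, 4).fired
        assert not evaluate_reminder(r, local, 4).fired

    def test_stale_evidence_fires_only_unbounded_lookback(self, cloud, local):
        # microalbumin result ~15 months old: outside the 12-month evidence
        # window but still evidence for the unbounded profile
        r = rec(
            ev("problem", "DIABETES"),
            ev("problem", "RENAL_DISEASE"),
            ev("lab", "MICROALBUMIN_LAB", days_ago=460),
        )
        assert not evaluate_reminder(r, cloud, 5).fired
        assert evaluate_reminder(r, local, 5).fired

    def test_esrd_or_ace_therapy_suppresses_advice(self, cloud):
        base = (
            ev("problem", "DIABETES"),
            ev("problem", "RENAL_DISEASE"),
            ev("lab", "MICROALBUMIN_LAB", days_ago=60),
        )
        assert evaluate_reminder(rec(*base), cloud, 5).fired
        assert not evaluate_reminder(rec(*base, ev("problem", "ESRD")), cloud, 5).fired
        assert not evaluate_reminder(rec(*base, ev("medication", "ACE_I", days_ago=0)), cloud, 5).fired
        assert not evaluate_reminder(rec(*base, ev("medication", "ARB", days_ago=0)), cloud, 5).fired

    def test_pregnancy_contraindication_recognized_only_by_extended_set(self, cloud, local):
        r = rec(
            ev("problem", "DIABETES"),
            ev("problem", "RENAL_DISEASE"),
            ev("lab", "MICROALBUMIN_LAB", days_ago=60),
            ev("problem", "PREGNANCY", days_ago=90),
        )
        assert evaluate_reminder(r, cloud, 6).fired  # ACE contraindicated -> ARB advice
        assert not evaluate_reminder(r, cloud, 5).fired
        assert evaluate_reminder(r, local, 5).fired  # pregnancy not in narrow contra set
        assert not evaluate_reminder(r, local, 6).fired


class TestExamRules:
    def test_eye_exam_exclusions_apply_only_to_local(self, cloud, local):
        r = rec(ev("problem", "DIABETES"), ev("problem", "BLINDNESS"))
        assert evaluate_reminder(r, cloud, 7).fired
        assert not evaluate_reminder(r, local, 7).fired
        r2 = rec(ev("problem", "DIABETES"), ev("exam", "EYE_CLINIC_VISIT", days_ago=100))
        assert evaluate_reminder(r2, cloud, 7).fired
        assert not evaluate_reminder(r2, local, 7).fired

    def test_recent_exams_satisfy_both(self, cloud, local):
        r = rec(
            ev("problem", "DIABETES"),
            ev("exam", "EYE_EXAM", days_ago=100),
            ev("exam", "FOOT_EXAM", days_ago=100),
        )
        for profile in (cloud, local):
            assert not evaluate_reminder(r, profile, 7).fired
            assert not evaluate_reminder(r, profile, 8).fired


class TestBloodPressureRule:
    def test_sitting_code_recognized_only_by_broad_set(self, cloud, local):
        r = rec(ev("lab", "BP_SYSTOLIC_SITTING", days_ago=30))
        assert evaluate_reminder(r, cloud, 9).fired
        assert not evaluate_reminder(r, local, 9).fired

    def test_standard_code_recognized_by_both(self, cloud, local):
        r = rec(ev("lab", "BP_SYSTOLIC", days_ago=30))
        assert not evaluate_reminder(r, cloud, 9).fired
        assert not evaluate_reminder(r, local, 9).fired


class TestAntiplateletRules:
    def test_extended_contraindication_splits_rules_10_and_11(self, cloud, local):
        r = rec(ev("problem", "CAD"), ev("problem", "ESOPHAGEAL_VARICES"))
        assert evaluate_reminder(r, cloud, 10).fired
        assert not evaluate_reminder(r, cloud, 11).fired
        assert evaluate_reminder(r, local, 11).fired
        assert not evaluate_reminder(r, local, 10).fired

    def test_core_contraindication_recognized_by_both(self, cloud, local):
        r = rec(ev("problem", "CAD"), ev("problem", "GI_BLEED"))
        for profile in (cloud, local):
            assert evaluate_reminder(r, profile, 10).fired
            assert not evaluate_reminder(r, profile, 11).fired

    def test_antiplatelet_therapy_suppresses_both(self, cloud):
        r = rec(ev("problem", "CAD"), ev("medication", "ANTIPLATELET", days_ago=0))
        assert not evaluate_reminder(r, cloud, 10).fired
        assert not evaluate_reminder(r, cloud, 11).fired


class TestEvaluateAll:
    def test_empty_record_fires_only_blood_pressure(self, cloud, local):
        for profile in (cloud, local):
            outs = evaluate_all(rec(), profile)
            assert [o.reminder_id for o in outs] == list(range(1, 12))
            assert [o.fired for o in outs] == [False] * 8 + [True, False, False]

    def test_bp_today_and_no_history_fires_nothing(self, cloud, local):
        r = rec(ev("lab", "BP_SYSTOLIC", days_ago=0))
        for profile in (cloud, local):
            assert not any(o.fired for o in evaluate_all(r, profile))

    def test_diabetic_with_all_care_up_to_date_fires_nothing(self, cloud, local):
        r = rec(
            ev("problem", "DIABETES"),
            ev("lab", "HBA1C_LAB", days_ago=30, value=6.8),
            ev("lab", "MICROALBUMIN_LAB", days_ago=30),
            ev("lab", "BP_SYSTOLIC", days_ago=30),
            ev("exam", "EYE_EXAM", days_ago=30),
            ev("exam", "FOOT_EXAM", days_ago=30),
        )
        for profile in (cloud, local):
            assert not any(o.fired for o in evaluate_all(r, profile))

    def test_message_is_verbatim_and_empty_iff_not_fired(self, cloud):
        r = rec(ev("problem", "DIABETES"))
        for out in evaluate_all(r, cloud):
            if out.fired:
                assert out.message == MESSAGES[out.reminder_id]
            else:
                assert out.message == ""

    def test_unknown_reminder_id_rejected(self, cloud):
        with pytest.raises(ValueError, match="reminder_id"):
            evaluate_reminder(rec(), cloud, 12)

    def test_evaluation_is_pure_and_repeatable(self, cloud):
        records = generate_cohort(SyntheticCohortConfig(n_visits=50, seed=3))
        first = [evaluate_all(r, cloud) for r in records]
        second = [evaluate_all(r, cloud) for r in records]
        assert first == second

    def test_mutual_exclusion_on_large_random_cohort(self, cloud, local):
        """At most one of {1,2,3}, {5,6}, {10,11} fires per visit/profile."""
        records = generate_cohort(SyntheticCohortConfig(n_visits=10_000, seed=42))
        for profile in (cloud, local):
            for record in records:
                fired = {o.reminder_id for o in evaluate_all(record, profile) if o.fired}
                assert len(fired & {1, 2, 3}) <= 1
                assert len(fired & {5, 6}) <= 1
                assert len(fired & {10, 11}) <= 1

    def test_removing_diabetes_evidence_turns_off_rules_1_to_8(self, cloud, local):
        diabetes_evidence = (
            concept_set("DIABETES").members
            | concept_set("GESTATIONAL_DIABETES").members
            | concept_set("DIABETES_ICD9").members
            | concept_set("ORAL_HYPOGLYCEMIC").members
            | concept_set("INSULIN").members
        )
        records = generate_cohort(SyntheticCohortConfig(n_visits=300, seed=8))
        for record in records:
            stripped = record.model_copy(
                update={
                    "events": tuple(
                        e for e in record.events if e.concept not in diabetes_evidence
                    )
                }
            )
            for profile in (cloud, local):
                fired = {o.reminder_id for o in evaluate_all(stripped, profile) if o.fired}
                assert fired <= {9, 10, 11}


class TestProfiles:
    def test_bp_code_sets_match_the_known_terminology_gap(self, cloud, local):
        sitting = code("BP_SYSTOLIC_SITTING")
        standard = code("BP_SYSTOLIC")
        assert standard in cloud.role("BP_LAB") and sitting not in cloud.role("BP_LAB")
        assert standard in local.role("BP_LAB") and sitting in local.role("BP_LAB")

    def test_local_applies_both_eye_exam_exclusions(self, cloud, local):
        assert local.eye_exam_exclusions == {"blindness", "eye_clinic_visit_within_12mo"}
        assert cloud.eye_exam_exclusions == frozenset()

    def test_profiles_differ_in_at_least_eight_parameters(self, cloud, local):
        diffs = 0
        diffs += cloud.diabetes_sources != local.diabetes_sources
        diffs += cloud.exclude_gestational_diabetes != local.exclude_gestational_diabetes
        diffs += cloud.angina_implies_cad != local.angina_implies_cad
        diffs += cloud.microalbumin_excludes_renal_disease != local.microalbumin_excludes_renal_disease
        diffs += cloud.ace_evidence_lookback_months != local.ace_evidence_lookback_months
        diffs += cloud.eye_exam_exclusions != local.eye_exam_exclusions
        for role in ("BP_LAB", "ACE_CONTRA", "ANTIPLATELET_CONTRA"):
            diffs += cloud.role(role).members != local.role(role).members
        assert diffs >= 8

    def test_equalized_profiles_produce_identical_outputs(self, cloud, local):
        equalized = dataclasses.replace(
            local,
            concept_sets=cloud.concept_sets,
            diabetes_sources=cloud.diabetes_sources,
            exclude_gestational_diabetes=cloud.exclude_gestational_diabetes,
            angina_implies_cad=cloud.angina_implies_cad,
            microalbumin_excludes_renal_disease=cloud.microalbumin_excludes_renal_disease,
            ace_evidence_lookback_months=cloud.ace_evidence_lookback_months,
            eye_exam_exclusions=cloud.eye_exam_exclusions,
            windows=cloud.windows,
        )
        assert equalized.equivalent_to(cloud)
        records = generate_cohort(SyntheticCohortConfig(n_visits=400, seed=5))
        for record in records:
            a = [(o.reminder_id, o.fired) for o in evaluate_all(record, cloud)]
            b = [(o.reminder_id, o.fired) for o in evaluate_all(record, equalized)]
            assert a == b
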