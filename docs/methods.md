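# Methods

## Overview

The package models a paired-evaluation study: two independently
parameterized implementations of 11 preventive-care reminder rules are
executed over the same visit-level patient records, and their fire/no-fire
decisions are compared per rule with chance-, bias- and prevalence-adjusted
agreement statistics. Three layers are deliberately separable: the record
model and I/O, the rule engine with its profiles, and the agreement
statistics (which operate on plain 2×2 counts and can be used on counts from
any source).

## Record model

A visit record is the chart snapshot visible to a rule engine on the visit
day: a flat list of dated events (problems, labs, active medication classes,
exams, discharge diagnoses), each carrying a `(system, code)` concept.
Dates are calendar dates; every rule is day-granular. Medication exposure is
class-level (`MEDCLASS` codes such as `ACE_I`, `ANTIPLATELET`) because every
rule tests class membership only. Contraindications and exclusions
(pregnancy, hyperkalemia, bleeding disorders, blindness, …) are coded
problems. Codes in unknown systems are preserved verbatim and never match a
concept set — deliberately mirroring how production engines silently ignore
terminology they do not recognise. HbA1c labs must carry a value in
(0, 25) %; other labs may be bare flags (a blood-pressure event's presence is
all the rules use).

## Month arithmetic and interval conventions

No guideline defines "6 months" operationally, so the package fixes one
convention and applies it everywhere: elapsed months = days / 30.4375 (the
mean Gregorian month, 487/16), kept as an exact rational. Interval phrases
are half-open: "within last N months" ⇔ elapsed < N; "over N months ago" ⇔
elapsed > N; "between A and B months ago" ⇔ A ≤ elapsed < B. Under these
conventions the three HbA1c rules (overdue / almost due / poorly controlled)
partition the timeline, so their mutual exclusion is structural. The
six-month boundary falls at 182.625 days: a result 182 days old is "within 6
months", one 183 days old is not, and tests pin both sides.

Same-date lab ties resolve to the larger value (conservative toward alerting
on a high HbA1c); a valued result outranks an unvalued one on the same day.

## Rule profiles

A `RuleProfile` names a concept set for every role a rule reads (22 roles)
and sets the behavioural switches: which diabetes sources count
(problem list / hypoglycemic medications / ICD9 discharge diagnoses),
whether gestational-diabetes-only histories are excluded, whether angina
implies CAD, whether established renal disease suppresses the
microalbumin-screening reminder, the microalbuminuria-evidence lookback for
the ACE-I/ARB rules (an integer number of months, or unbounded), and which
eye-exam exclusions apply (blindness, eye-clinic visit within 12 months).

The built-in `CLOUD` profile is the consortium-style end: problem-list-only
diabetes excluding gestational diabetes, angina counted as CAD, renal
exclusion on screening, 12-month evidence window, no eye-exam exclusions, a
blood-pressure set holding only the plain systolic LOINC code (8480-6), and
extended contraindication sets (ACE-I: allergy + pregnancy + hyperkalemia;
antiplatelet: bleeding disorder, thrombocytopenia, GI bleed, esophageal
varices, coagulation-factor deficiency, cerebral hemorrhage). The `LOCAL`
profile is the home-grown end: all three diabetes sources, no gestational
exclusion, angina not CAD, no renal exclusion, unbounded evidence window,
both eye-exam exclusions, both systolic codes (8480-6 and the sitting
variant 8459-0), and narrow contraindication sets (ACE-I: allergy only;
antiplatelet: the core three). The profiles differ in nine parameters;
equalizing them yields behaviourally identical engines, which is tested.

Two genuinely open points were resolved as follows and made switchable:
the ACE-I advice rule requires *some* microalbuminuria lab evidence under
both profiles, differing only in the lookback (a pure no-time-limit reading
is obtained by the unbounded setting); and "established renal disease" and
"chronic renal disease" resolve to the same concept set, with ESRD separate.
The blood-pressure rule applies to every visit: the record model carries no
age, so no adult cutoff is enforced. Rule messages are fixed verbatim
strings, newline-separated including their action bullets.

Except for LOINC 8480-6/8459-0 and SNOMED CT 194828000 (angina), every code
in the shipped vocabulary is a project-invented placeholder (flagged
"synthetic placeholder" in its display text): the concept lists of the
original engines are not public, and nothing in the analysis depends on real
code values — only on set membership.

## Agreement statistics

With per-rule counts a (both fired), b (first only), c (second only),
d (neither): P₀ = (a+d)/n; Pe = [(a+b)(a+c)+(c+d)(b+d)]/n²;
κ = (P₀−Pe)/(1−Pe); BI = (c−b)/n; PI = (a−d)/n; PABAK = 2·P₀−1. κ is
reported as undefined (None) when Pe = 1 (both engines constant), rather
than 0 or an exception. The identity PABAK − κ = (1−P₀)(2·Pe−1)/(1−Pe)
implies PABAK ≥ κ exactly when Pe ≥ ½; both the identity and a brute-force
all-pairs chance-agreement oracle for κ are property-tested. Landis–Koch
bands use cut-points 0.81/0.61/0.41/0.21/0.01 with boundaries included in
the upper band (0.61 is "substantial"); values ≤ 0 fall below the published
scale and are labelled "poor/none". BI is defined second-minus-first
(`(c − b)/n`), matching the reporting convention of the tabulated results
this package reproduces.

Confidence intervals for PABAK use the percentile bootstrap: n visits
resampled with replacement, PABAK recomputed per replicate, interval at the
α/2 and 1−α/2 quantiles (default 10,000 replicates, α = 0.05). Because PABAK
depends on a resample only through its four cell counts, replicates are
drawn as multinomial counts — distributionally identical to index
resampling and far cheaper. Resampling is per rule with independent
sub-streams derived from one user seed; marginal intervals are identical to
joint-across-rules resampling. All statistics are kept at full precision;
rounding (half away from zero, 2 decimals) happens only in the presentation
layer.

## Synthetic cohorts

The generator emulates the statistical shape of a primary-care
reminder-agreement study: a configurable number of visits (default 405,
spread over a 92-day window), subpopulations with diabetes (default 45%,
plus 3% gestational-only), CAD (18%, plus 3% angina-without-CAD), and renal
disease (15%, of which 15% ESRD); active medication classes; and labs/exams
present with per-type probabilities whose recency is uniform over 0–24
months, which places probability mass on both sides of every rule boundary
(3/5/6/11/12 months). HbA1c values are Normal(7.5, 1.5) truncated to
(4, 15) %. One visit per synthetic patient; no within-patient correlation,
no demographics (no rule reads them). Defaults live in
`data/default_cohort_config.json` and were chosen once to put per-rule
firing prevalences in a realistic range; they are stand-ins, not a claim
about any real cohort, so passing pipeline tests demonstrate correctness of
the machinery, not clinical performance on real records.

Nine config fields are "discordance knobs" — patterns on which the two
built-in profiles disagree (sitting-coded blood pressure, gestational-only
or medication-only diabetes evidence, angina coding, a renal subpopulation,
extended-set-only contraindications, blindness, eye-clinic visits). With all
nine at zero (`concordant_config()`), the profiles agree on every generated
visit, giving an exact null. `concordance_stress_cohort(class, intensity,
…)` activates one discrepancy class at a time: terminology perturbs only
rule 9; local practice variation perturbs rules 1–8 and 10–11; temporal
windows perturb rules 4–6 (the renal subpopulation that arms the lookback
difference also arms the renal exclusion of rule 4); exclusions perturb
rules 4–7 and 10–11. Tests assert each class's discordance stays inside its
subset.

## Problem sizes and numerical choices

Property tests use seeded generators (hypothesis with explicit example
budgets; numpy `default_rng` elsewhere). The κ oracle sweep is exhaustive
for tables with n ≤ 20 and sampled for n ≤ 50. Structural rule invariants
are checked over a 10,000-visit synthetic cohort; discordance-structure
tests use 1,000–2,000 visits, enough to make every relevant cell non-empty
with margin. Bootstrap regression tests use the full 10,000 replicates at
n = 405.

## Limitations

The rule logic is a faithful re-expression of guideline conditions, not an
emulation of any production rule language; real engines' concept lists are
reconstructed from three publicly known codes plus placeholders; the
generator's independence assumptions (labs independent of each other and of
conditions) are simplifications that make closed-form expectations testable
but understate the correlation structure of real charts.
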