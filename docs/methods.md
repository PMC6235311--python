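# Methods

## Classification model

Identification is a two-step procedure mirroring facility-based near-miss
audit. Step one screens admissions for potentially life-threatening
conditions (PLTC): a listed underlying complication (severe postpartum
hemorrhage, severe pre-eclampsia, eclampsia, uterine rupture, severe
abortion complications, sepsis/severe systemic infection), a critical
intervention (any blood products, laparotomy other than cesarean section),
or ICU admission. The condition list is configuration data
(`ClassifierConfig.pltc_causes`), not code, so sites can extend it. Step two
classifies each enrolled woman at discharge, independently under each tool:
*maternal death* if she died, *maternal near miss* if she survived with at
least one criterion fulfilled, *none* otherwise. Severe maternal outcome
(SMO) = MNM + MD.

Every criterion is a pure predicate over the record. Missing values are
distinct from false/zero and never fulfil a criterion — classification
rests on documented evidence, which is exactly why a death can be invisible
to a tool. By default a death with no fulfilled criterion is counted under
*neither* tool (and surfaced as a warning), which keeps the dual-tool
arithmetic honest; `count_all_deaths=True` implements the alternative
convention in which every maternal death is an SMO by definition. Both
behaviours are needed: the first reproduces documentation-gap discordance,
the second matches the conceptual definition of SMO.

Criterion-level conventions worth stating:

* **Transfusion** is one shared criterion with tool-specific thresholds —
  ≥5 units of blood (WHO) vs ≥2 units of red cells (SSA) — applied to a
  single `transfusion_units` field, since abstracted charts rarely separate
  products. Both thresholds are overridable (`EngineConfig`).
* **Eclampsia vs uncontrollable fit** are distinct: a single eclamptic
  convulsion fires only the SSA eclampsia criterion; status epilepticus
  fires the shared "uncontrollable fit/total paralysis" criterion under
  both tools.
* **Sepsis** accepts the abstractor's adjudicated flag or is computed from
  raw vitals: a clinical sign of infection plus at least three of
  temperature >38 °C or <36 °C, respiratory rate >20/min, pulse >90/min,
  WBC >12,000.
* **Eclampsia (computed path)**: the operational definition has ambiguous
  operator precedence; it is implemented as (diastolic BP ≥90 mmHg OR
  proteinuria 3+) AND (convulsion OR coma), switchable off via
  `EngineConfig.eclampsia_strict`.
* **Severe pre-eclampsia with ICU admission** is the conjunction of the
  diagnosis flag and ICU admission.
* Oxygen saturation <90% requires a documented episode duration >60 min;
  continuity of measurement is not required (any qualifying documented
  episode counts).
* Creatinine is stored in µmol/l; mg/dl input is converted (×88.4).
* Per-criterion counts in the discordance table are non-exclusive multiset
  counts (a woman with several criteria appears on each row). For
  SSA-added criteria, the "WHO" column counts the subset of those women who
  fulfil *any* WHO criterion; the remainder is the per-criterion
  "not fulfilling WHO" column.

## Indicator panel

All indicators are stored at full precision and rounded to one decimal only
in rendered output. Mortality index is MD/(MD+MNM)×100 everywhere,
including per-cause rows; published per-cause tables are not always
internally consistent with this formula, and the package deliberately
implements the formula rather than any particular printed cell. With zero
SMO the mortality index is undefined (reported as null, never 0). SM012
(dysfunction or death on arrival or within 12 h) plus intrahospital SMO
partition the SMO cases; the SM012 mortality index uses deaths among SM012
cases over SM012 cases, validated by the identity that the case-weighted
average of the SM012 and intrahospital indices equals the overall index.

Process indicators are computed over condition-specific target populations
drawn from *all* enrolled records, not only SMO cases (e.g. magnesium
sulfate coverage among all eclamptic women); the SMO-proportion item inside
each population follows the original WHO classification. Empty populations
yield undefined coverages rather than zeros.

## Synthetic cohort generator

The generator emulates the structure of a two-hospital referral PLTC cohort
(default n = 1054 women, 7404 live births). It is cause-first: an
underlying complication is drawn from the PLTC cause mix, then criteria,
interventions and transfusion exposure conditionally on cause, which gives
realistic criterion co-occurrence (ruptured uteri arrive with laparotomy,
usually blood and often hysterectomy; eclamptic women convulse and
sometimes add WHO-recognised organ dysfunction). Severity has two layers:

* a cause-specific probability of being **WHO-severe**, in which case the
  woman draws a cause-specific bundle of WHO criteria (at least one
  guaranteed via a signature criterion). For severe pre-eclampsia the
  probability is higher given ICU admission, reflecting that ICU transfer
  selects the sickest women;
* cause-conditional probabilities for the SSA condition criteria,
  laparotomy, and transfusion (units drawn from a fixed distribution among
  transfused women: 229/118/35/15/9 across 1/2/3–4/5+ units per 406
  transfused), which generate the SSA-only surplus.

Deaths follow a logistic model on the number of fulfilled SSA criteria
(slope 0.85 per criterion). The intercept is not a committed constant: it
is solved by bisection against the *exact* expected death count, computed
from the Poisson-binomial distribution of the criterion count within each
cause × severity × transfusion stratum (`expected_margins`). Changing any
prevalence therefore preserves the configured death target without
re-tuning. Women who die without a documented WHO criterion receive
terminal resuscitation (CPR), making maternal deaths recognisable under
both tools — except, in the default paper-faithful mode, two
deterministically planted "documentation-gap" deaths (one pulmonary edema
only, one two-unit transfusion only) that the WHO tool cannot see.

Referral and 12-hour timing are drawn conditionally on outcome (deaths are
referred with probability 0.893, near misses 0.611; SM012 is more likely
for referred women), and process-of-care items conditionally on the
relevant condition (magnesium sulfate 0.947 among eclamptic women, with
other anticonvulsants nested among magnesium users; uterotonics drawn as
any-coverage 0.727 then type mix; cesarean prophylaxis 0.972; therapeutic
antibiotics 0.794 in sepsis).

All calibration constants are data (`CauseProfile` defaults), tuned once
against the reference cohort's margins using the analytic expectation
calculator — not against stochastic test runs — and committed. The
committed defaults imply expected margins of 621.6 SSA SMO, 154.6 WHO SMO,
28.0 deaths and 406.6 transfused women, with ~92% of SSA-only cases
attributable to eclampsia, sepsis or the transfusion-threshold difference.

**What the generator does not emulate.** Labs are populated only when their
criterion fires (the joint distribution of laboratory values with clinical
signs is otherwise unconstrained); WHO-exclusive criteria (PaO₂/FiO₂,
bilirubin, pH, lactate, vasoactive drugs, dialysis) have zero prevalence by
default, as in settings where they are unmeasurable; there is no admission
process or length-of-stay beyond the 12-hour dichotomy, no multi-admission
linkage, and no between-hospital structure. Referral margins follow the
cohort-characteristics table; the referred share *within* SM012 cases is
consequently lower than some published hospital-access figures, which are
not mutually consistent with those characteristics. Passing tests on
synthetic cohorts therefore demonstrates correctness of the classification
and indicator arithmetic under realistic margins — not validity of any
epidemiological conclusion about real facilities.

## Numerical and testing choices

Determinism: one `numpy` Generator seeded from the configuration drives all
draws in a fixed order; the same configuration and seed reproduce an
identical cohort, and the CLI pipeline is byte-reproducible given a seed.
The criteria engine is validated against an independently coded truth table
by exhaustive enumeration over a 12-field reduced record space (24,576
records × both tools). Parameter recovery uses 100 replicate cohorts
(~1054 records each, ~25 s total), comparing Monte-Carlo means against the
calibration targets at three standard errors; the cohort size and replicate
count were chosen so those standard errors are small relative to the
margins being recovered.

## Known limitations

* The validator flags inconsistencies but never resolves them; conflicting
  chart entries are an upstream adjudication problem.
* No severity grading beyond binary criterion fulfilment, no ICD-MM cause
  coding, no confidence intervals on indicators, and no per-hospital
  denominators.
* The PLTC screen reflects the published condition list; ectopic pregnancy,
  for instance, enrols only via interventions (blood, laparotomy, ICU)
  unless the screening list is extended.
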