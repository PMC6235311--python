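# mnmkit — maternal near-miss classification and indicator pipeline

Maternal near miss (MNM) — a woman who nearly died but survived a
life-threatening complication of pregnancy, childbirth, or the 42 days after
termination of pregnancy — has become a standard complement to maternal
mortality for monitoring the quality of obstetric care, especially where
deaths alone are too few to analyse. The WHO near-miss tool defines MNM
through 25 clinical, laboratory-based and management-based criteria. In
low-resource facilities many of those criteria are rarely measurable (blood
gases, lactate, dialysis, continuous vasoactive drugs), so a sub-Saharan
Africa (SSA) adaptation keeps 19 of the WHO criteria, lowers the transfusion
threshold from ≥5 units of blood to ≥2 units of red cells, and adds locally
identifiable conditions (eclampsia, uterine rupture, sepsis/severe systemic
infection, pulmonary edema, severe abortion complications, severe malaria,
severe pre-eclampsia with ICU admission, laparotomy other than cesarean
section), for 27 criteria in total.

`mnmkit` is for obstetric-audit and facility-surveillance teams who have
per-woman discharge abstractions and want reproducible, side-by-side
classification under both tools. It provides:

* **records** — a validated per-woman schema (signs, labs, interventions,
  underlying cause, 12-hour timing, referral, outcome) with a CSV dialect
  and YAML data dictionary; missing values are first-class and never fulfil
  a criterion;
* **criteria** — every criterion of both tools as an independently testable
  predicate, with thresholds exactly as published (respiratory rate >40 or
  <6/min, SpO₂ <90% for >60 min, creatinine ≥300 µmol/l, platelets
  <50,000/ml, pH <7.1, ...);
* **classify** — the two-step identification (screen women with potentially
  life-threatening conditions, then determine MNM / maternal death / severe
  maternal outcome at discharge) and the per-criterion WHO-vs-SSA
  discordance table;
* **indicators** — the full near-miss indicator panel, cause-specific
  breakdown, condition-specific process indicators, and a
  transfusion-threshold sensitivity sweep;
* **synthetic** — a calibrated cause-first cohort generator emulating a
  referral-hospital PLTC cohort, for end-to-end testing and methods work.

The panel indicators, for MNM and maternal death (MD) counts against the
live-birth denominator *LB*:

```
SMO ratio        = 1000 · (MNM + MD) / LB        (severe maternal outcomes)
MNM ratio        = 1000 · MNM / LB
MNM : MD ratio   = MNM / MD
Mortality index  = 100 · MD / (MNM + MD)         (lower ⇒ better care)
```

plus hospital-access indicators over SM012 (SMO cases whose organ
dysfunction or death was present on arrival or within 12 h of admission)
and their intrahospital complement.

## Worked example

Recompute a facility's indicator panel from aggregate counts (594 near
misses and 28 deaths under the SSA tool, 7404 live births):

```python
>>> from mnmkit import panel_from_counts
>>> panel = panel_from_counts(tool="ssa", mnm=594, md=28, live_births=7404)
>>> panel.to_dict()["smo_ratio"], panel.to_dict()["mnm_ratio"]
(84.0, 80.2)
>>> panel.to_dict()["mnm_md_ratio"], panel.to_dict()["mortality_index_pct"]
(21.2, 4.5)
```

84 women per 1000 live births had a severe maternal outcome; for every
maternal death there were 21.2 near-miss survivors, and 4.5% of women who
reached a life-threatening state died.

Or run the whole pipeline on a generated cohort from the shell:

```
$ mnmkit report --seed 1 -o demo/
```

which writes `cohort.csv`, `classification.csv`, `discordance.csv`,
`indicator_panel.csv`, cause and process indicator tables, a transfusion
sweep and a reproducibility manifest. For seed 1 the panel reads (one
column per tool):

```
indicator                             who     ssa
smo                                 142.0   600.0
mnm                                 121.0   577.0
md                                   21.0    23.0
smo_ratio                            19.2    81.0
mnm_ratio                            16.3    77.9
mnm_md_ratio                          5.8    25.1
mortality_index_pct                  14.8     3.8
```

and the discordance table shows where the SSA surplus comes from — women
the WHO tool misses almost entirely through eclampsia, sepsis and the lower
transfusion threshold:

```
criterion                n_ssa  n_who  cases_not_fulfilling_who
eclampsia                  219     26                       193
sepsis_severe_infection    141     20                       121
transfusion                182     39                       143
total_smo                  600    142                       458
```

Two generated deaths (pulmonary edema only; a two-unit transfusion only)
fulfil no WHO criterion and are flagged on stderr rather than silently
absorbed — the `--count-all-deaths` flag forces every maternal death into
both tools' SMO counts instead.

## Layout

```
src/mnmkit/
  records.py     patient-level schema + validation
  criteria.py    WHO / SSA criterion catalogue and predicates
  classify.py    PLTC screen, cohort classification, discordance
  indicators.py  indicator panel, cause breakdown, process indicators, sweep
  synthetic.py   calibrated synthetic-cohort generator
  io.py          cohort CSV dialect, data dictionary
  reports.py     report tables (CSV / text)
  cli.py         `mnmkit` command-line interface
docs/methods.md  model, calibration and design notes
```
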