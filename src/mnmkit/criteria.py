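"""WHO and sub-Saharan Africa maternal near-miss criteria as testable predicates.

The original WHO near-miss tool lists 25 criteria in three groups (clinical,
laboratory-based, management-based).  The sub-Saharan Africa (SSA) adaptation
keeps 19 of them, drops six that depend on laboratory or intensive-care
capacity rarely available in low-resource facilities (PaO2/FiO2, bilirubin,
pH, lactate, continuous vasoactive drugs, dialysis), and adds eight locally
identifiable ones (eclampsia, uterine rupture, sepsis/severe systemic
infection, pulmonary edema, severe abortion complications, severe malaria,
severe pre-eclampsia with ICU admission, laparotomy other than cesarean
section), for 27 in total.  The transfusion criterion is shared but with a
tool-specific threshold: >=5 units of blood (WHO) versus >=2 units of red
cells (SSA).

Each criterion is a pure predicate over a :class:`~mnmkit.records.WomanRecord`;
missing values never fulfil a criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .records import WomanRecord

__all__ = [
    "Criterion",
    "CriterionResult",
    "EngineConfig",
    "CATALOG",
    "evaluate",
    "any_fired",
    "fired_keys",
    "criterion",
    "shared_keys",
    "who_only_keys",
    "ssa_only_keys",
    "catalog_table",
]

TOOLS = ("who", "ssa")


@dataclass(frozen=True)
class EngineConfig:
    """Tunable thresholds of the criteria engine.

    Defaults are the printed thresholds of the two tools.  ``eclampsia_strict``
    selects the operational definition for computed (non-flag) eclampsia:
    (diastolic BP >=90 mmHg OR proteinuria 3+) AND (convulsion OR coma).
    When off, the adjudicated flag alone is honoured.
    """

    who_transfusion_threshold: int = 5
    ssa_transfusion_threshold: int = 2
    eclampsia_strict: bool = True


DEFAULT_CONFIG = EngineConfig()


@dataclass(frozen=True)
class Criterion:
    """One near-miss criterion: identity, tool membership, predicate."""

    key: str
    label: str
    group: str  # clinical | laboratory | management
    in_who: bool
    in_ssa: bool
    predicate: Callable[[WomanRecord, str, EngineConfig], Optional[dict]]

    def evaluate(
        self, record: WomanRecord, tool: str, config: EngineConfig = DEFAULT_CONFIG
    ) -> "CriterionResult":
        evidence = self.predicate(record, tool, config)
        return CriterionResult(
            key=self.key, fired=evidence is not None, tool=tool, evidence=evidence or {}
        )


@dataclass(frozen=True)
class CriterionResult:
    """Outcome of evaluating one criterion for one woman under one tool."""

    key: str
    fired: bool
    tool: str
    evidence: dict = field(default_factory=dict)


def _flag(name: str):
    """Predicate for an abstractor-adjudicated boolean sign."""

    def pred(r: WomanRecord, tool: str, cfg: EngineConfig):
        return {name: True} if getattr(r, name) else None

    return pred


def _respiratory_rate(r: WomanRecord, tool: str, cfg: EngineConfig):
    if r.respiratory_rate is not None and (r.respiratory_rate > 40 or r.respiratory_rate < 6):
        return {"respiratory_rate": r.respiratory_rate}
    if r.abnormal_respiratory_rate:
        return {"abnormal_respiratory_rate": True}
    return None


def _oxygen_saturation(r: WomanRecord, tool: str, cfg: EngineConfig):
    if (
        r.oxygen_saturation_pct is not None
        and r.oxygen_saturation_pct < 90
        and r.oxygen_saturation_duration_min is not None
        and r.oxygen_saturation_duration_min > 60
    ):
        return {
            "oxygen_saturation_pct": r.oxygen_saturation_pct,
            "oxygen_saturation_duration_min": r.oxygen_saturation_duration_min,
        }
    return None


def _threshold(name: str, op: str, cutoff: float):
    def pred(r: WomanRecord, tool: str, cfg: EngineConfig):
        value = getattr(r, name)
        if value is None:
            return None
        hit = value >= cutoff if op == "ge" else value > cutoff if op == "gt" else value < cutoff
        return {name: value} if hit else None

    return pred


def _sepsis(r: WomanRecord, tool: str, cfg: EngineConfig):
    """Adjudicated sepsis flag, or the operational definition from raw vitals:
    a clinical sign of infection plus >=3 of temp >38/<36 C, RR >20, pulse >90,
    WBC >12,000."""
    if r.sepsis_severe_infection:
        return {"sepsis_severe_infection": True}
    if not r.infection_sign:
        return None
    hits = {}
    if r.temperature_c is not None and (r.temperature_c > 38 or r.temperature_c < 36):
        hits["temperature_c"] = r.temperature_c
    if r.respiratory_rate is not None and r.respiratory_rate > 20:
        hits["respiratory_rate"] = r.respiratory_rate
    if r.pulse_bpm is not None and r.pulse_bpm > 90:
        hits["pulse_bpm"] = r.pulse_bpm
    if r.wbc_per_ul is not None and r.wbc_per_ul > 12000:
        hits["wbc_per_ul"] = r.wbc_per_ul
    if len(hits) >= 3:
        hits["infection_sign"] = True
        return hits
    return None


def _eclampsia(r: WomanRecord, tool: str, cfg: EngineConfig):
    """Adjudicated eclampsia flag, or the computed operational definition
    (diastolic >=90 or proteinuria 3+) and (convulsion or coma)."""
    if r.eclampsia:
        return {"eclampsia": True}
    if not cfg.eclampsia_strict:
        return None
    hypertensive = (r.diastolic_bp_mmhg is not None and r.diastolic_bp_mmhg >= 90) or (
        r.proteinuria_dipstick is not None and r.proteinuria_dipstick >= 3
    )
    neuro = r.convulsion or r.coma
    if hypertensive and neuro:
        ev = {"convulsion": r.convulsion, "coma": r.coma}
        if r.diastolic_bp_mmhg is not None:
            ev["diastolic_bp_mmhg"] = r.diastolic_bp_mmhg
        if r.proteinuria_dipstick is not None:
            ev["proteinuria_dipstick"] = r.proteinuria_dipstick
        return ev
    return None


def _severe_pe_icu(r: WomanRecord, tool: str, cfg: EngineConfig):
    if r.severe_preeclampsia_flag and r.icu_admission:
        return {"severe_preeclampsia_flag": True, "icu_admission": True}
    return None


def _transfusion(r: WomanRecord, tool: str, cfg: EngineConfig):
    threshold = (
        cfg.who_transfusion_threshold if tool == "who" else cfg.ssa_transfusion_threshold
    )
    if r.transfusion_units >= threshold:
        return {"transfusion_units": r.transfusion_units, "threshold": threshold}
    return None


CATALOG: tuple[Criterion, ...] = (
    # -- clinical, shared -----------------------------------------------------
    Criterion("acute_cyanosis", "Acute cyanosis", "clinical", True, True, _flag("acute_cyanosis")),
    Criterion("gasping", "Gasping", "clinical", True, True, _flag("gasping")),
    Criterion(
        "respiratory_rate_abnormal",
        "Respiratory rate >40 or <6/min",
        "clinical",
        True,
        True,
        _respiratory_rate,
    ),
    Criterion("shock", "Shock", "clinical", True, True, _flag("shock")),
    Criterion(
        "oliguria_nonresponsive",
        "Oliguria nonresponsive to fluids or diuretics",
        "clinical",
        True,
        True,
        _flag("oliguria_nonresponsive"),
    ),
    Criterion(
        "failure_to_form_clots",
        "Failure to form clots",
        "clinical",
        True,
        True,
        _flag("failure_to_form_clots"),
    ),
    Criterion(
        "loss_of_consciousness_12h",
        "Loss of consciousness lasting ≥12 h",
        "clinical",
        True,
        True,
        _flag("loss_of_consciousness_12h"),
    ),
    Criterion("cardiac_arrest", "Cardiac arrest", "clinical", True, True, _flag("cardiac_arrest")),
    Criterion("stroke", "Stroke", "clinical", True, True, _flag("stroke")),
    Criterion(
        "uncontrollable_fit",
        "Uncontrollable fit/total paralysis",
        "clinical",
        True,
        True,
        _flag("uncontrollable_fit"),
    ),
    Criterion(
        "jaundice_with_preeclampsia",
        "Jaundice in the presence of pre-eclampsia",
        "clinical",
        True,
        True,
        _flag("jaundice_with_preeclampsia"),
    ),
    # -- clinical, SSA additions ---------------------------------------------
    Criterion("eclampsia", "Eclampsia", "clinical", False, True, _eclampsia),
    Criterion("uterine_rupture", "Uterine rupture", "clinical", False, True, _flag("uterine_rupture")),
    Criterion(
        "sepsis_severe_infection",
        "Sepsis or severe systemic infection",
        "clinical",
        False,
        True,
        _sepsis,
    ),
    Criterion("pulmonary_edema", "Pulmonary edema", "clinical", False, True, _flag("pulmonary_edema")),
    Criterion(
        "severe_abortion_complication",
        "Severe abortion complications",
        "clinical",
        False,
        True,
        _flag("severe_abortion_complication"),
    ),
    Criterion("severe_malaria", "Severe malaria", "clinical", False, True, _flag("severe_malaria")),
    Criterion(
        "severe_preeclampsia_icu",
        "Severe pre-eclampsia with ICU admission",
        "clinical",
        False,
        True,
        _severe_pe_icu,
    ),
    # -- laboratory -----------------------------------------------------------
    Criterion(
        "oxygen_saturation_low",
        "Oxygen saturation <90% for >60 minutes",
        "laboratory",
        True,
        True,
        _oxygen_saturation,
    ),
    Criterion(
        "pao2_fio2_low",
        "PaO2/FiO2 <200 mmHg",
        "laboratory",
        True,
        False,
        _threshold("pao2_fio2_mmhg", "lt", 200),
    ),
    Criterion(
        "creatinine_high",
        "Creatinine ≥300 μmol/l or ≥3.5 mg/dl",
        "laboratory",
        True,
        True,
        _threshold("creatinine_umol_l", "ge", 300),
    ),
    Criterion(
        "bilirubin_high",
        "Bilirubin >100 μmol/l or >6.0 mg/dl",
        "laboratory",
        True,
        False,
        _threshold("bilirubin_umol_l", "gt", 100),
    ),
    Criterion("ph_low", "pH <7.1", "laboratory", True, False, _threshold("ph", "lt", 7.1)),
    Criterion(
        "lactate_high", "Lactate >5 mEq/ml", "laboratory", True, False, _threshold("lactate_meq_ml", "gt", 5)
    ),
    Criterion(
        "thrombocytopenia",
        "Acute thrombocytopenia (<50,000 platelets/ml)",
        "laboratory",
        True,
        True,
        _threshold("platelets_per_ml", "lt", 50000),
    ),
    Criterion(
        "ketoacidosis_unconscious",
        "Loss of consciousness and ketoacids in urine",
        "laboratory",
        True,
        True,
        _flag("ketoacids_with_unconsciousness"),
    ),
    # -- management -----------------------------------------------------------
    Criterion(
        "vasoactive_drugs",
        "Use of continuous vasoactive drugs",
        "management",
        True,
        False,
        _flag("continuous_vasoactive_drugs"),
    ),
    Criterion(
        "hysterectomy_infection_hemorrhage",
        "Hysterectomy following infection or haemorrhage",
        "management",
        True,
        True,
        _flag("hysterectomy_for_infection_or_hemorrhage"),
    ),
    Criterion(
        "transfusion",
        "Transfusion of ≥5 units of blood (WHO) / ≥2 units of red blood cells (SSA)",
        "management",
        True,
        True,
        _transfusion,
    ),
    Criterion(
        "intubation_60min",
        "Intubation and ventilation for ≥60 min not related to anaesthesia",
        "management",
        True,
        True,
        _flag("intubation_ge_60min_nonanesthetic"),
    ),
    Criterion(
        "dialysis",
        "Dialysis for acute renal failure",
        "management",
        True,
        False,
        _flag("dialysis_acute_renal_failure"),
    ),
    Criterion(
        "cpr", "Cardio-pulmonary resuscitation", "management", True, True, _flag("cpr")
    ),
    Criterion(
        "laparotomy_other_than_cs",
        "Laparotomy other than caesarean section",
        "management",
        False,
        True,
        _flag("laparotomy_other_than_cs"),
    ),
)

_BY_KEY = {c.key: c for c in CATALOG}


def criterion(key: str) -> Criterion:
    """Look up a criterion by key."""
    return _BY_KEY[key]


def _members(tool: str) -> tuple[Criterion, ...]:
    if tool == "who":
        return tuple(c for c in CATALOG if c.in_who)
    if tool == "ssa":
        return tuple(c for c in CATALOG if c.in_ssa)
    raise ValueError(f"unknown tool {tool!r}; expected one of {TOOLS}")


def evaluate(
    record: WomanRecord, tool: str, config: EngineConfig = DEFAULT_CONFIG
) -> list[CriterionResult]:
    """Evaluate every criterion of ``tool`` against one record.

    Returns one :class:`CriterionResult` per member criterion, fired or not,
    in catalogue order.  Missing values never fire a criterion.
    """
    return [c.evaluate(record, tool, config) for c in _members(tool)]


def fired_keys(
    record: WomanRecord, tool: str, config: EngineConfig = DEFAULT_CONFIG
) -> list[str]:
    """Keys of the criteria that fire for this record under ``tool``."""
    return [res.key for res in evaluate(record, tool, config) if res.fired]


def any_fired(
    record: WomanRecord, tool: str, config: EngineConfig = DEFAULT_CONFIG
) -> bool:
    """True iff at least one criterion of ``tool`` fires for this record."""
    return any(
        c.predicate(record, tool, config) is not None for c in _members(tool)
    )


def shared_keys() -> list[str]:
    return [c.key for c in CATALOG if c.in_who and c.in_ssa]


def who_only_keys() -> list[str]:
    return [c.key for c in CATALOG if c.in_who and not c.in_ssa]


def ssa_only_keys() -> list[str]:
    return [c.key for c in CATALOG if c.in_ssa and not c.in_who]


def catalog_table() -> list[dict]:
    """The criteria catalogue as plain rows (key, label, group, tool flags,
    thresholds) for export as a YAML/CSV reference card."""
    rows = []
    for c in CATALOG:
        row = {
            "key": c.key,
            "label": c.label,
            "group": c.group,
            "in_who": c.in_who,
            "in_ssa": c.in_ssa,
        }
        if c.key == "transfusion":
            row["who_threshold_units"] = DEFAULT_CONFIG.who_transfusion_threshold
            row["ssa_threshold_units"] = DEFAULT_CONFIG.ssa_transfusion_threshold
        rows.append(row)
    return rows
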