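"""Patient-level record schema for facility-based maternal near-miss review.

One :class:`WomanRecord` holds everything abstracted from a woman's chart at
discharge: demographics, obstetric history, the underlying complication,
pre-adjudicated clinical signs, laboratory values, management interventions,
process-of-care items, timing of organ dysfunction relative to admission,
referral status, and vital outcome.

Missing values are first-class and distinct from ``False``/``0``: a lab that
was never drawn is ``None``, and downstream criteria treat it as *not
fulfilled* — the classification rests on documented chart evidence only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional

__all__ = [
    "WomanRecord",
    "ValidationFinding",
    "validate_record",
    "MODES_OF_DELIVERY",
    "FETAL_OUTCOMES",
    "UNDERLYING_CAUSES",
    "OUTCOMES",
    "UTEROTONIC_TYPES",
    "CREATININE_MGDL_TO_UMOL",
]

MODES_OF_DELIVERY = frozenset(
    {"vaginal", "cesarean_section", "laparotomy", "abortion", "no_delivery"}
)
FETAL_OUTCOMES = frozenset({"alive", "stillbirth", "not_applicable"})
UNDERLYING_CAUSES = frozenset(
    {
        "severe_preeclampsia",
        "eclampsia_cause",
        "abortion_related",
        "ectopic_pregnancy",
        "abruptio_placenta",
        "placenta_previa",
        "uterine_rupture_cause",
        "severe_pph",
        "other_hemorrhage",
        "sepsis_cause",
        "other",
        "none",
    }
)
OUTCOMES = frozenset({"discharged_alive", "maternal_death"})
UTEROTONIC_TYPES = frozenset({"oxytocin", "ergometrine", "misoprostol", "other"})

#: conversion factor for creatinine reported in mg/dl
CREATININE_MGDL_TO_UMOL = 88.4


@dataclass
class WomanRecord:
    """One woman's admission, as abstracted from her chart at discharge.

    Clinical-sign flags are booleans pre-adjudicated by the chart abstractor.
    Respiratory rate, oxygen saturation and the laboratory values are kept
    numeric so that the criteria engine can apply the printed thresholds
    itself; the corresponding adjudicated flag (where one exists) is also
    honoured, whichever is present.
    """

    id: str

    # -- demographics / obstetric history -----------------------------------
    age_years: Optional[int] = None
    referred_from_other_facility: bool = False
    antenatal_care: Optional[bool] = None
    gestational_age_weeks: Optional[int] = None
    parity: Optional[int] = None
    mode_of_delivery: str = "no_delivery"
    fetal_outcome: str = "not_applicable"
    underlying_cause: str = "none"
    anemia: bool = False
    previous_cesarean: bool = False

    # -- clinical signs (abstractor-adjudicated flags) ----------------------
    acute_cyanosis: bool = False
    gasping: bool = False
    abnormal_respiratory_rate: bool = False
    respiratory_rate: Optional[float] = None  # breaths/min
    shock: bool = False
    oliguria_nonresponsive: bool = False
    failure_to_form_clots: bool = False
    loss_of_consciousness_12h: bool = False
    cardiac_arrest: bool = False
    stroke: bool = False
    uncontrollable_fit: bool = False
    jaundice_with_preeclampsia: bool = False
    eclampsia: bool = False
    uterine_rupture: bool = False
    sepsis_severe_infection: bool = False
    pulmonary_edema: bool = False
    severe_abortion_complication: bool = False
    severe_malaria: bool = False
    severe_preeclampsia_flag: bool = False

    # -- raw vitals for the sepsis / eclampsia operational definitions ------
    infection_sign: bool = False
    temperature_c: Optional[float] = None
    pulse_bpm: Optional[float] = None
    wbc_per_ul: Optional[float] = None
    diastolic_bp_mmhg: Optional[float] = None
    proteinuria_dipstick: Optional[int] = None  # 0..4 plus scale
    convulsion: bool = False
    coma: bool = False

    # -- laboratory values --------------------------------------------------
    oxygen_saturation_pct: Optional[float] = None
    oxygen_saturation_duration_min: Optional[float] = None
    pao2_fio2_mmhg: Optional[float] = None
    creatinine_umol_l: Optional[float] = None
    bilirubin_umol_l: Optional[float] = None
    ph: Optional[float] = None
    lactate_meq_ml: Optional[float] = None
    platelets_per_ml: Optional[float] = None
    ketoacids_with_unconsciousness: bool = False

    # -- management interventions -------------------------------------------
    transfusion_units: int = 0
    continuous_vasoactive_drugs: bool = False
    hysterectomy_for_infection_or_hemorrhage: bool = False
    intubation_ge_60min_nonanesthetic: bool = False
    dialysis_acute_renal_failure: bool = False
    cpr: bool = False
    laparotomy_other_than_cs: bool = False
    icu_admission: bool = False

    # -- process of care ------------------------------------------------------
    uterotonics_given: frozenset = field(default_factory=frozenset)
    magnesium_sulfate: bool = False
    other_anticonvulsant: bool = False
    prophylactic_antibiotic_at_cs: bool = False
    parenteral_therapeutic_antibiotics: bool = False
    hysterectomy_any: bool = False

    # -- timing / outcome -----------------------------------------------------
    dysfunction_within_12h_of_admission: bool = False
    outcome: str = "discharged_alive"

    def __post_init__(self) -> None:
        if not isinstance(self.uterotonics_given, frozenset):
            self.uterotonics_given = frozenset(self.uterotonics_given)


@dataclass(frozen=True)
class ValidationFinding:
    """A single validation finding: the offending field, severity, message."""

    field: str
    severity: str  # "error" | "warning"
    message: str


def _err(f: str, msg: str) -> ValidationFinding:
    return ValidationFinding(f, "error", msg)


def _warn(f: str, msg: str) -> ValidationFinding:
    return ValidationFinding(f, "warning", msg)


# numeric range checks: (field, low, high) inclusive bounds, applied when present
_NUMERIC_RANGES = [
    ("age_years", 10, 60),
    ("gestational_age_weeks", 4, 45),
    ("parity", 0, 30),
    ("respiratory_rate", 0, 120),
    ("oxygen_saturation_pct", 0, 100),
    ("oxygen_saturation_duration_min", 0, None),
    ("pao2_fio2_mmhg", 0, None),
    ("creatinine_umol_l", 0, None),
    ("bilirubin_umol_l", 0, None),
    ("ph", 6.0, 8.0),
    ("lactate_meq_ml", 0, None),
    ("platelets_per_ml", 0, None),
    ("temperature_c", 25, 45),
    ("pulse_bpm", 0, 300),
    ("wbc_per_ul", 0, None),
    ("diastolic_bp_mmhg", 0, 200),
    ("proteinuria_dipstick", 0, 4),
]


def validate_record(record: WomanRecord) -> list[ValidationFinding]:
    """Check one record for schema violations and internal inconsistencies.

    Returns a list of findings rather than raising: ``error`` findings are
    out-of-range numerics or unknown enum tokens, ``warning`` findings are
    combinations that are internally inconsistent but conceivable in messy
    chart data (the validator flags, it never resolves).  A fully consistent
    record yields an empty list.  Findings are sorted by field name so the
    result is independent of evaluation order.
    """
    findings: list[ValidationFinding] = []

    if not record.id or not str(record.id).strip():
        findings.append(_err("id", "id must be a non-empty string"))

    enum_checks = [
        ("mode_of_delivery", MODES_OF_DELIVERY),
        ("fetal_outcome", FETAL_OUTCOMES),
        ("underlying_cause", UNDERLYING_CAUSES),
        ("outcome", OUTCOMES),
    ]
    for fname, allowed in enum_checks:
        value = getattr(record, fname)
        if value not in allowed:
            findings.append(_err(fname, f"unknown value {value!r}"))

    unknown_ut = set(record.uterotonics_given) - UTEROTONIC_TYPES
    if unknown_ut:
        findings.append(
            _err("uterotonics_given", f"unknown uterotonic tokens {sorted(unknown_ut)}")
        )

    for fname, lo, hi in _NUMERIC_RANGES:
        value = getattr(record, fname)
        if value is None:
            continue
        if isinstance(value, float) and math.isnan(value):
            findings.append(_err(fname, "NaN is not a valid value; use missing"))
            continue
        if (lo is not None and value < lo) or (hi is not None and value > hi):
            findings.append(_err(fname, f"value {value} outside [{lo}, {hi}]"))

    if not isinstance(record.transfusion_units, int) or record.transfusion_units < 0:
        findings.append(
            _err("transfusion_units", "must be a non-negative integer unit count")
        )

    # ---- consistency warnings ---------------------------------------------
    if record.mode_of_delivery == "no_delivery" and record.fetal_outcome != "not_applicable":
        findings.append(
            _err("fetal_outcome", "must be not_applicable when no delivery occurred")
        )
    if (
        record.oxygen_saturation_pct is not None
        and record.oxygen_saturation_pct < 90
        and record.oxygen_saturation_duration_min is None
    ):
        findings.append(
            _warn(
                "oxygen_saturation_duration_min",
                "saturation <90% documented without an episode duration",
            )
        )
    if record.prophylactic_antibiotic_at_cs and record.mode_of_delivery != "cesarean_section":
        findings.append(
            _warn(
                "prophylactic_antibiotic_at_cs",
                "prophylaxis at cesarean recorded but mode of delivery is not cesarean",
            )
        )
    if record.magnesium_sulfate and not (
        record.eclampsia or record.severe_preeclampsia_flag or record.convulsion
    ):
        findings.append(
            _warn(
                "magnesium_sulfate",
                "magnesium sulfate given without documented (pre-)eclampsia",
            )
        )
    if record.eclampsia and not (
        record.convulsion
        or record.coma
        or record.severe_preeclampsia_flag
        or (record.diastolic_bp_mmhg is not None and record.diastolic_bp_mmhg >= 90)
        or (record.proteinuria_dipstick is not None and record.proteinuria_dipstick >= 3)
    ):
        findings.append(
            _warn(
                "eclampsia",
                "eclampsia flagged without hypertensive context or convulsion/coma evidence",
            )
        )
    if record.severe_abortion_complication and record.underlying_cause not in (
        "abortion_related",
        "other",
        "none",
    ):
        findings.append(
            _warn(
                "severe_abortion_complication",
                "severe abortion complication flagged under a non-abortion cause",
            )
        )
    if record.hysterectomy_for_infection_or_hemorrhage and not record.hysterectomy_any:
        findings.append(
            _warn(
                "hysterectomy_any",
                "criterion-level hysterectomy set but process-of-care hysterectomy unset",
            )
        )
    if record.outcome == "maternal_death" and record.mode_of_delivery == "no_delivery":
        # plausible (antepartum death) — no finding; kept as an explicit no-op
        pass

    findings.sort(key=lambda f: (f.field, f.severity, f.message))
    return findings


def record_field_names() -> list[str]:
    """Column order of the tabular representation (CSV header)."""
    return [f.name for f in fields(WomanRecord)]
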