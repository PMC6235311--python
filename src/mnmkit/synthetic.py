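"""Synthetic facility cohorts for exercising the near-miss pipeline.

The generator emulates the structure of a two-hospital referral cohort of
women admitted with potentially life-threatening conditions (PLTC).
Generation is cause-first: each woman is assigned an underlying complication
(eclampsia, severe pre-eclampsia, sepsis, uterine rupture, the hemorrhagic
causes, ...), and her criteria, interventions and transfusion exposure are
drawn conditionally on that cause.  This induces realistic co-occurrence:
a ruptured uterus brings a laparotomy, often a hysterectomy and blood
products; an eclamptic woman brings convulsions and sometimes organ
dysfunction recognised by the original WHO tool.

Two layers govern severity:

* a cause-specific probability of being "WHO-severe" — carrying at least one
  criterion of the original WHO tool, drawn from a cause-specific bundle —
  which calibrates how many women each cause contributes to the WHO column;
* independent cause-specific probabilities for the adapted sub-Saharan
  Africa (SSA) tool's condition criteria (eclampsia, sepsis, ...), the lower
  transfusion threshold, and laparotomy, which generate the SSA surplus.

Deaths are drawn from a logistic model on the number of fired SSA criteria;
the intercept is calibrated analytically (not by trial runs) so that the
expected number of deaths matches the configured target.  Women who die
receive terminal resuscitation (CPR) when no WHO criterion is otherwise
documented, reflecting that maternal deaths are almost always recognisable
under both tools.  In paper-faithful mode two "documentation-gap" deaths are
planted deterministically — one with pulmonary edema only, one with a
two-unit transfusion only — which the WHO tool cannot see.

All calibration constants are data (module-level defaults, overridable), not
code.  :func:`expected_margins` computes the exact expectations the defaults
imply, so calibration never relies on chasing stochastic test output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .records import WomanRecord, validate_record

__all__ = [
    "CauseProfile",
    "CohortConfig",
    "default_config",
    "generate",
    "expected_margins",
    "calibrate_death_intercept",
    "margin_report",
]

# SSA-only condition criteria that are plain adjudicated flags
_CONDITION_FLAGS = (
    "eclampsia",
    "uterine_rupture",
    "sepsis_severe_infection",
    "pulmonary_edema",
    "severe_abortion_complication",
    "severe_malaria",
)

# how a drawn criterion key materialises on the record
_SETTERS: dict[str, dict] = {
    "acute_cyanosis": {"acute_cyanosis": True},
    "gasping": {"gasping": True},
    "respiratory_rate_abnormal": {"respiratory_rate": 46.0},
    "shock": {"shock": True},
    "oliguria_nonresponsive": {"oliguria_nonresponsive": True},
    "failure_to_form_clots": {"failure_to_form_clots": True},
    "loss_of_consciousness_12h": {"loss_of_consciousness_12h": True},
    "cardiac_arrest": {"cardiac_arrest": True},
    "stroke": {"stroke": True},
    "uncontrollable_fit": {"uncontrollable_fit": True},
    "jaundice_with_preeclampsia": {"jaundice_with_preeclampsia": True},
    "oxygen_saturation_low": {
        "oxygen_saturation_pct": 85.0,
        "oxygen_saturation_duration_min": 90.0,
    },
    "creatinine_high": {"creatinine_umol_l": 340.0},
    "thrombocytopenia": {"platelets_per_ml": 30000.0},
    "ketoacidosis_unconscious": {"ketoacids_with_unconsciousness": True},
    "hysterectomy_infection_hemorrhage": {
        "hysterectomy_for_infection_or_hemorrhage": True,
        "hysterectomy_any": True,
    },
    "intubation_60min": {"intubation_ge_60min_nonanesthetic": True},
    "cpr": {"cpr": True},
    "eclampsia": {"eclampsia": True, "convulsion": True, "diastolic_bp_mmhg": 100.0},
    "uterine_rupture": {"uterine_rupture": True},
    "sepsis_severe_infection": {"sepsis_severe_infection": True, "infection_sign": True},
    "pulmonary_edema": {"pulmonary_edema": True},
    "severe_abortion_complication": {"severe_abortion_complication": True},
    "severe_malaria": {"severe_malaria": True},
    "laparotomy_other_than_cs": {"laparotomy_other_than_cs": True},
}


@dataclass(frozen=True)
class CauseProfile:
    """Cause-conditional generation parameters for one underlying complication.

    ``weight``: expected share of the PLTC cohort (unnormalised).
    ``p_who_severe``: probability of carrying a WHO-tool criterion bundle.
    ``bundle``: per-criterion firing probabilities given WHO-severe; if none
    fires, ``signature`` fires (the bundle guarantees at least one).
    ``flags``: probabilities for SSA condition flags (unconditional).
    ``p_laparotomy`` / ``p_icu`` / ``p_transfused``: intervention exposure.
    ``pe_flag``: whether women of this cause carry the severe pre-eclampsia
    diagnosis flag (ICU admission then fires the SSA criterion).
    ``p_who_severe_icu``: WHO-severity probability for ICU-admitted women of
    a ``pe_flag`` cause (ICU admissions are sicker); ``None`` means no lift.
    """

    weight: float
    p_who_severe: float
    bundle: dict[str, float]
    signature: str
    flags: dict[str, float] = field(default_factory=dict)
    p_laparotomy: float = 0.0
    p_icu: float = 0.02
    pe_flag: bool = False
    p_who_severe_icu: Optional[float] = None
    p_transfused: float = 0.2
    mode_dist: dict[str, float] = field(
        default_factory=lambda: {"vaginal": 0.6, "cesarean_section": 0.3, "no_delivery": 0.1}
    )
    p_stillbirth: float = 0.15
    p_anemia: float = 0.33


# ---------------------------------------------------------------------------
# default calibration constants
#
# Cause weights are expected PLTC headcounts (they are normalised internally).
# Bundle and flag probabilities were calibrated once, with
# ``expected_margins``, against the per-criterion, per-cause and total margins
# of the reference facility cohort (1054 PLTC women, 622 SSA / 154 WHO severe
# maternal outcomes, 28 deaths, 406 transfused) and then committed.
# ---------------------------------------------------------------------------

_DEFAULT_CAUSES: dict[str, CauseProfile] = {
    "eclampsia_cause": CauseProfile(
        weight=227,
        p_who_severe=0.089,
        bundle={
            "loss_of_consciousness_12h": 0.22,
            "respiratory_rate_abnormal": 0.28,
            "oxygen_saturation_low": 0.18,
            "thrombocytopenia": 0.18,
            "stroke": 0.07,
            "uncontrollable_fit": 0.20,
            "jaundice_with_preeclampsia": 0.10,
            "intubation_60min": 0.22,
            "shock": 0.10,
            "cardiac_arrest": 0.05,
        },
        signature="loss_of_consciousness_12h",
        flags={"eclampsia": 1.0, "pulmonary_edema": 0.012},
        p_icu=0.05,
        p_transfused=0.30,
        mode_dist={"vaginal": 0.62, "cesarean_section": 0.33, "no_delivery": 0.05},
        p_stillbirth=0.25,
    ),
    "severe_preeclampsia": CauseProfile(
        weight=190,
        p_who_severe=0.042,
        p_who_severe_icu=0.47,
        bundle={
            "thrombocytopenia": 0.30,
            "jaundice_with_preeclampsia": 0.08,
            "respiratory_rate_abnormal": 0.20,
            "oxygen_saturation_low": 0.15,
            "stroke": 0.05,
            "failure_to_form_clots": 0.15,
            "intubation_60min": 0.10,
            "shock": 0.10,
            "oliguria_nonresponsive": 0.05,
        },
        signature="thrombocytopenia",
        flags={"pulmonary_edema": 0.008},
        p_icu=0.09,
        pe_flag=True,
        p_transfused=0.18,
        mode_dist={"vaginal": 0.54, "cesarean_section": 0.42, "no_delivery": 0.04},
        p_stillbirth=0.2,
    ),
    "sepsis_cause": CauseProfile(
        weight=135,
        p_who_severe=0.115,
        bundle={
            "respiratory_rate_abnormal": 0.45,
            "oxygen_saturation_low": 0.30,
            "hysterectomy_infection_hemorrhage": 0.25,
            "intubation_60min": 0.15,
            "gasping": 0.15,
            "creatinine_high": 0.05,
            "oliguria_nonresponsive": 0.03,
            "acute_cyanosis": 0.08,
        },
        signature="respiratory_rate_abnormal",
        flags={"sepsis_severe_infection": 0.895},
        p_icu=0.04,
        p_transfused=0.18,
        mode_dist={
            "vaginal": 0.65,
            "cesarean_section": 0.25,
            "abortion": 0.05,
            "no_delivery": 0.05,
        },
    ),
    "severe_pph": CauseProfile(
        weight=77,
        p_who_severe=0.213,
        bundle={
            "shock": 0.55,
            "hysterectomy_infection_hemorrhage": 0.35,
            "failure_to_form_clots": 0.20,
        },
        signature="shock",
        p_icu=0.03,
        p_transfused=0.88,
        mode_dist={"vaginal": 0.80, "cesarean_section": 0.20},
    ),
    "uterine_rupture_cause": CauseProfile(
        weight=53,
        p_who_severe=0.736,
        bundle={"hysterectomy_infection_hemorrhage": 1.0, "shock": 0.15},
        signature="hysterectomy_infection_hemorrhage",
        flags={"uterine_rupture": 1.0},
        p_laparotomy=1.0,
        p_icu=0.04,
        p_transfused=0.95,
        mode_dist={"laparotomy": 0.85, "cesarean_section": 0.15},
        p_stillbirth=0.75,
    ),
    "abortion_related": CauseProfile(
        weight=60,
        p_who_severe=0.062,
        bundle={"shock": 0.60},
        signature="shock",
        flags={"severe_abortion_complication": 0.24, "sepsis_severe_infection": 0.32},
        p_icu=0.02,
        p_transfused=0.50,
        mode_dist={"abortion": 1.0},
    ),
    "ectopic_pregnancy": CauseProfile(
        weight=20,
        p_who_severe=0.089,
        bundle={"shock": 0.80},
        signature="shock",
        p_laparotomy=0.72,
        p_icu=0.02,
        p_transfused=0.92,
        mode_dist={"no_delivery": 1.0},
    ),
    "abruptio_placenta": CauseProfile(
        weight=40,
        p_who_severe=0.124,
        bundle={"shock": 0.50, "failure_to_form_clots": 0.35, "thrombocytopenia": 0.20},
        signature="shock",
        p_icu=0.02,
        p_transfused=0.70,
        mode_dist={"cesarean_section": 0.60, "vaginal": 0.40},
        p_stillbirth=0.6,
    ),
    "placenta_previa": CauseProfile(
        weight=50,
        p_who_severe=0.195,
        bundle={"shock": 0.60, "failure_to_form_clots": 0.20},
        signature="shock",
        p_icu=0.02,
        p_transfused=0.68,
        mode_dist={"cesarean_section": 0.85, "vaginal": 0.15},
    ),
    "other_hemorrhage": CauseProfile(
        weight=35,
        p_who_severe=0.036,
        bundle={"shock": 0.70},
        signature="shock",
        p_icu=0.02,
        p_transfused=0.75,
        mode_dist={"vaginal": 0.60, "cesarean_section": 0.40},
    ),
    "other": CauseProfile(
        weight=167,
        p_who_severe=0.036,
        bundle={
            "respiratory_rate_abnormal": 0.25,
            "oxygen_saturation_low": 0.30,
            "gasping": 0.30,
            "acute_cyanosis": 0.15,
            "cardiac_arrest": 0.25,
            "intubation_60min": 0.20,
            "loss_of_consciousness_12h": 0.20,
            "ketoacidosis_unconscious": 0.10,
            "stroke": 0.10,
        },
        signature="intubation_60min",
        flags={"pulmonary_edema": 0.030, "sepsis_severe_infection": 0.06},
        p_laparotomy=0.015,
        p_icu=0.03,
        p_transfused=0.15,
        mode_dist={"vaginal": 0.50, "cesarean_section": 0.32, "no_delivery": 0.18},
    ),
}

#: transfused-unit distribution (units -> weight among transfused women)
_DEFAULT_UNIT_DIST: dict[int, float] = {1: 229, 2: 118, 3: 35, 4: 15, 5: 6, 6: 2, 7: 1}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic PLTC cohort generator."""

    n_pltc: int = 1054
    live_births: int = 7404
    seed: int = 0
    causes: dict[str, CauseProfile] = field(default_factory=lambda: dict(_DEFAULT_CAUSES))
    unit_dist: dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_UNIT_DIST))
    # logistic death model on the number of fired SSA criteria
    death_slope: float = 0.85
    death_intercept: Optional[float] = None  # None -> calibrated to target_deaths
    target_deaths: int = 28
    paper_faithful: bool = True  # plant the two documentation-gap deaths
    # referral and 12-hour-timing margins
    p_referred_death: float = 0.893
    p_referred_mnm: float = 0.611
    p_referred_other: float = 0.45
    p_sm012_death: float = 0.92
    p_sm012_referred: float = 0.93
    p_sm012_not_referred: float = 0.72
    # process-of-care coverage
    p_mgso4_eclampsia: float = 0.947
    p_other_anticonvulsant_given_mgso4: float = 0.145
    p_any_uterotonic_pph: float = 0.727
    uterotonic_cond: dict[str, float] = field(
        default_factory=lambda: {
            "oxytocin": 0.821,
            "ergometrine": 0.322,
            "misoprostol": 0.358,
            "other": 0.107,
        }
    )
    p_prophylactic_antibiotic_cs: float = 0.972
    p_therapeutic_antibiotics_sepsis: float = 0.794
    p_therapeutic_antibiotics_other: float = 0.08
    p_antenatal: float = 0.29
    p_previous_cesarean: float = 0.026

    def validate(self) -> None:
        if self.n_pltc <= 0:
            raise ValueError("n_pltc must be positive")
        if self.live_births <= 0:
            raise ValueError("live_births must be positive")
        if not self.causes:
            raise ValueError("at least one cause profile required")
        for name, prof in self.causes.items():
            if prof.weight < 0:
                raise ValueError(f"{name}: negative weight")
            probs = (
                [prof.p_who_severe, prof.p_laparotomy, prof.p_icu, prof.p_transfused,
                 prof.p_stillbirth, prof.p_anemia]
                + list(prof.bundle.values())
                + list(prof.flags.values())
                + list(prof.mode_dist.values())
                + ([prof.p_who_severe_icu] if prof.p_who_severe_icu is not None else [])
            )
            for p in probs:
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}: probability {p} outside [0, 1]")
            for key in prof.bundle:
                if key not in _SETTERS:
                    raise ValueError(f"{name}: unknown bundle criterion {key!r}")
            for key in prof.flags:
                if key not in _CONDITION_FLAGS:
                    raise ValueError(f"{name}: unknown condition flag {key!r}")
            if prof.signature not in prof.bundle:
                raise ValueError(f"{name}: signature must be a bundle member")
            if abs(sum(prof.mode_dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name}: mode_dist must sum to 1")
        if any(w < 0 for w in self.unit_dist.values()) or sum(self.unit_dist.values()) <= 0:
            raise ValueError("unit_dist weights must be non-negative and sum > 0")
        for p in (
            self.p_referred_death, self.p_referred_mnm, self.p_referred_other,
            self.p_sm012_death, self.p_sm012_referred, self.p_sm012_not_referred,
            self.p_mgso4_eclampsia, self.p_any_uterotonic_pph,
            self.p_prophylactic_antibiotic_cs, self.p_therapeutic_antibiotics_sepsis,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The committed default configuration (optionally with field overrides)."""
    return replace(CohortConfig(seed=seed), **overrides)


# ---------------------------------------------------------------------------
# analytic expectations
# ---------------------------------------------------------------------------


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _poisson_binomial(probs: Sequence[float]) -> list[float]:
    """Distribution of the number of successes of independent Bernoullis."""
    dist = [1.0]
    for p in probs:
        nxt = [0.0] * (len(dist) + 1)
        for k, w in enumerate(dist):
            nxt[k] += w * (1 - p)
            nxt[k + 1] += w * p
        dist = nxt
    return dist


def _bundle_dist(bundle: dict[str, float]) -> list[float]:
    """Bundle-count distribution with the at-least-one guarantee."""
    dist = _poisson_binomial(list(bundle.values()))
    if len(dist) > 1:
        dist[1] += dist[0]
        dist[0] = 0.0
    return dist


def _convolve(a: list[float], b: list[float]) -> list[float]:
    out = [0.0] * (len(a) + len(b) - 1)
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            out[i + j] += x * y
    return out


def _unit_cat_probs(config: CohortConfig, p_transfused: float) -> tuple[float, float, float]:
    """(P[u in 2..4], P[u >= 5], P[u <= 1]) for one cause."""
    total = sum(config.unit_dist.values())
    p24 = p_transfused * sum(w for u, w in config.unit_dist.items() if 2 <= u <= 4) / total
    p5 = p_transfused * sum(w for u, w in config.unit_dist.items() if u >= 5) / total
    return p24, p5, 1.0 - p24 - p5


def expected_margins(config: CohortConfig, death_intercept: Optional[float] = None) -> dict:
    """Exact expectations implied by the configuration.

    Returns expected per-criterion SSA counts, SSA/WHO severe-maternal-outcome
    counts, deaths, transfused women, and the expected attributable share of
    SSA-only cases (those explained by eclampsia, sepsis, or the transfusion
    threshold).  Used for calibration and for :func:`margin_report`; the death
    components require the calibrated intercept (see
    :func:`calibrate_death_intercept`).
    """
    config.validate()
    a = death_intercept if death_intercept is not None else config.death_intercept
    slope = config.death_slope
    n_ordinary = config.n_pltc - (2 if config.paper_faithful else 0)
    wsum = sum(p.weight for p in config.causes.values())

    crit_exp: dict[str, float] = {}
    ssa_smo = who_smo = deaths = transfused = 0.0
    ssa_only = ssa_only_attr = 0.0

    for cause, prof in config.causes.items():
        n_c = n_ordinary * prof.weight / wsum
        transfused += n_c * prof.p_transfused
        p24, p5, p01 = _unit_cat_probs(config, prof.p_transfused)
        icu_states = [(1, prof.p_icu), (0, 1 - prof.p_icu)] if prof.pe_flag else [(0, 1.0)]
        flag_probs = dict(prof.flags)
        if prof.p_laparotomy:
            flag_probs["laparotomy_other_than_cs"] = prof.p_laparotomy

        def p_w_given_icu(icu_det: int) -> float:
            if icu_det and prof.p_who_severe_icu is not None:
                return prof.p_who_severe_icu
            return prof.p_who_severe

        p_w_mean = sum(p * p_w_given_icu(icu) for icu, p in icu_states)

        # per-criterion marginal expectations (stratum-independent pieces)
        for key, p in flag_probs.items():
            crit_exp[key] = crit_exp.get(key, 0.0) + n_c * p
        p_bundle_none = math.prod(1 - p for p in prof.bundle.values())
        for key, p in prof.bundle.items():
            extra = p_bundle_none if key == prof.signature else 0.0
            crit_exp[key] = crit_exp.get(key, 0.0) + n_c * p_w_mean * (p + extra)
        crit_exp["transfusion"] = crit_exp.get("transfusion", 0.0) + n_c * (p24 + p5)
        if prof.pe_flag:
            crit_exp["severe_preeclampsia_icu"] = (
                crit_exp.get("severe_preeclampsia_icu", 0.0) + n_c * prof.p_icu
            )

        flag_dist = _poisson_binomial(list(flag_probs.values()))
        bdist = _bundle_dist(prof.bundle)
        for icu_det, p_icu_s in icu_states:
            for w_state in (1, 0):
                p_w = p_w_given_icu(icu_det) if w_state else 1 - p_w_given_icu(icu_det)
                for u_tag, u_det, p_u in (("u24", 1, p24), ("u5", 1, p5), ("u01", 0, p01)):
                    u_is5 = u_tag == "u5"
                    p_str = p_w * p_u * p_icu_s
                    if p_str <= 0:
                        continue
                    n_str = n_c * p_str
                    det = u_det + icu_det
                    kdist = flag_dist
                    if w_state:
                        kdist = _convolve(kdist, bdist)
                    # deaths and escalation need the intercept
                    if a is not None:
                        e_death = sum(
                            pk * _sigmoid(a + slope * (k + det))
                            for k, pk in enumerate(kdist)
                        )
                        deaths += n_str * e_death
                    else:
                        e_death = 0.0
                    p_k0 = kdist[0] if det == 0 else 0.0
                    p_any = 1.0 - p_k0
                    # SSA SMO: any criterion, or a death escalated into one
                    d_k0 = _sigmoid(a) if (a is not None and det == 0) else 0.0
                    ssa_smo += n_str * (p_any + p_k0 * d_k0)
                    if w_state or u_is5:
                        who_smo += n_str
                    else:
                        who_smo += n_str * e_death  # escalated deaths
                        # terminal resuscitation recorded for escalated deaths
                        crit_exp["cpr"] = crit_exp.get("cpr", 0.0) + n_str * e_death
                        # SSA-only survivors in this stratum
                        p_so = p_any - (e_death - p_k0 * d_k0)
                        ssa_only += n_str * max(p_so, 0.0)
                        if u_det:  # 2-4 units: transfusion-threshold attributable
                            ssa_only_attr += n_str * max(p_so, 0.0)
                        else:
                            p_big3 = 1.0 - (1 - flag_probs.get("eclampsia", 0.0)) * (
                                1 - flag_probs.get("sepsis_severe_infection", 0.0)
                            )
                            # approximation: attributable share among SSA-only
                            ssa_only_attr += n_str * max(p_so, 0.0) * (
                                p_big3 / p_any if p_any > 0 else 0.0
                            )

    if config.paper_faithful:
        ssa_smo += 2
        deaths += 2
        transfused += 1
        ssa_only += 2
        ssa_only_attr += 1  # the two-unit-transfusion death
        crit_exp["transfusion"] = crit_exp.get("transfusion", 0.0) + 1
        crit_exp["pulmonary_edema"] = crit_exp.get("pulmonary_edema", 0.0) + 1

    return {
        "criterion_expected": crit_exp,
        "ssa_smo": ssa_smo,
        "who_smo": who_smo,
        "deaths": deaths,
        "transfused": transfused,
        "ssa_only": ssa_only,
        "ssa_only_attributable": ssa_only_attr,
    }


def calibrate_death_intercept(config: CohortConfig) -> float:
    """Solve the logistic intercept so expected deaths match the target.

    The expectation is computed exactly from the per-stratum distribution of
    the SSA criterion count (a Poisson-binomial mixture), so the calibration
    is deterministic and independent of any simulation run.
    """
    target = float(config.target_deaths) - (2 if config.paper_faithful else 0)

    def f(a: float) -> float:
        return expected_margins(config, death_intercept=a)["deaths"] - (
            target + (2 if config.paper_faithful else 0)
        )

    lo, hi = -20.0, 5.0
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise ValueError("death target not attainable with this configuration")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _draw_cat(rng: np.random.Generator, dist: dict) -> object:
    keys = list(dist.keys())
    probs = np.asarray([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


def _planted_deaths(start_index: int) -> list[WomanRecord]:
    """The two documentation-gap deaths the WHO tool cannot see."""
    a = WomanRecord(
        id=f"w{start_index:04d}",
        age_years=28,
        underlying_cause="other",
        pulmonary_edema=True,
        referred_from_other_facility=True,
        dysfunction_within_12h_of_admission=True,
        mode_of_delivery="vaginal",
        fetal_outcome="stillbirth",
        outcome="maternal_death",
    )
    b = WomanRecord(
        id=f"w{start_index + 1:04d}",
        age_years=24,
        underlying_cause="severe_pph",
        transfusion_units=2,
        referred_from_other_facility=True,
        dysfunction_within_12h_of_admission=True,
        mode_of_delivery="vaginal",
        fetal_outcome="alive",
        anemia=True,
        outcome="maternal_death",
    )
    return [a, b]


def generate(config: CohortConfig) -> list[WomanRecord]:
    """Generate one validated PLTC cohort.

    Deterministic for a fixed configuration and seed.  Every record passes
    :func:`mnmkit.records.validate_record` with no error-level findings.
    """
    from .criteria import fired_keys  # deferred: avoid import cycle

    config.validate()
    a = (
        config.death_intercept
        if config.death_intercept is not None
        else calibrate_death_intercept(config)
    )
    rng = np.random.default_rng(config.seed)
    n_ordinary = config.n_pltc - (2 if config.paper_faithful else 0)
    wsum = sum(p.weight for p in config.causes.values())
    cause_dist = {name: p.weight / wsum for name, p in config.causes.items()}
    unit_keys = sorted(config.unit_dist)
    unit_probs = np.asarray([config.unit_dist[u] for u in unit_keys], dtype=float)
    unit_probs /= unit_probs.sum()

    records: list[WomanRecord] = []
    for i in range(n_ordinary):
        cause = _draw_cat(rng, cause_dist)
        prof = config.causes[cause]
        kw: dict = {"id": f"w{i + 1:04d}", "underlying_cause": cause}

        icu = rng.random() < prof.p_icu
        p_w = (
            prof.p_who_severe_icu
            if (icu and prof.p_who_severe_icu is not None)
            else prof.p_who_severe
        )
        fired: set[str] = set()
        if rng.random() < p_w:
            bundle_fired = [k for k, p in prof.bundle.items() if rng.random() < p]
            if not bundle_fired:
                bundle_fired = [prof.signature]
            fired.update(bundle_fired)
        for key, p in prof.flags.items():
            if rng.random() < p:
                fired.add(key)
        if prof.p_laparotomy and rng.random() < prof.p_laparotomy:
            fired.add("laparotomy_other_than_cs")
        for key in fired:
            kw.update(_SETTERS[key])

        if prof.pe_flag:
            kw["severe_preeclampsia_flag"] = True
        if icu:
            kw["icu_admission"] = True
        if rng.random() < prof.p_transfused:
            kw["transfusion_units"] = int(unit_keys[rng.choice(len(unit_keys), p=unit_probs)])

        # demographics and delivery
        kw["age_years"] = int(np.clip(round(rng.normal(25.4, 6.1)), 15, 49))
        kw["antenatal_care"] = bool(rng.random() < config.p_antenatal)
        kw["gestational_age_weeks"] = int(np.clip(round(rng.normal(36.0, 4.5)), 5, 43))
        kw["parity"] = int(min(rng.poisson(2.2), 12))
        kw["anemia"] = bool(rng.random() < prof.p_anemia)
        kw["previous_cesarean"] = bool(rng.random() < config.p_previous_cesarean)
        mode = _draw_cat(rng, prof.mode_dist)
        kw["mode_of_delivery"] = mode
        if mode in ("no_delivery", "abortion") or cause == "ectopic_pregnancy":
            kw["fetal_outcome"] = "not_applicable"
        else:
            kw["fetal_outcome"] = (
                "stillbirth" if rng.random() < prof.p_stillbirth else "alive"
            )

        # process of care
        if kw.get("eclampsia"):
            if rng.random() < config.p_mgso4_eclampsia:
                kw["magnesium_sulfate"] = True
                if rng.random() < config.p_other_anticonvulsant_given_mgso4:
                    kw["other_anticonvulsant"] = True
        if cause == "severe_pph" and rng.random() < config.p_any_uterotonic_pph:
            given = {
                u for u, p in config.uterotonic_cond.items() if rng.random() < p
            } or {"oxytocin"}
            kw["uterotonics_given"] = frozenset(given)
        if mode == "cesarean_section" and rng.random() < config.p_prophylactic_antibiotic_cs:
            kw["prophylactic_antibiotic_at_cs"] = True
        p_abx = (
            config.p_therapeutic_antibiotics_sepsis
            if kw.get("sepsis_severe_infection")
            else config.p_therapeutic_antibiotics_other
        )
        if rng.random() < p_abx:
            kw["parenteral_therapeutic_antibiotics"] = True

        record = WomanRecord(**kw)
        k = len(fired_keys(record, "ssa"))
        dies = rng.random() < _sigmoid(a + config.death_slope * k)
        referred_p = (
            config.p_referred_death
            if dies
            else (config.p_referred_mnm if k > 0 else config.p_referred_other)
        )
        referred = rng.random() < referred_p
        if dies:
            sm012 = rng.random() < config.p_sm012_death
        else:
            sm012 = rng.random() < (
                config.p_sm012_referred if referred else config.p_sm012_not_referred
            )
        updates: dict = {
            "referred_from_other_facility": bool(referred),
            "dysfunction_within_12h_of_admission": bool(sm012),
        }
        if dies:
            updates["outcome"] = "maternal_death"
            if not fired_keys(record, "who"):
                updates["cpr"] = True  # terminal resuscitation
        for fname, val in updates.items():
            setattr(record, fname, val)
        records.append(record)

    if config.paper_faithful:
        records.extend(_planted_deaths(n_ordinary + 1))
    return records


def margin_report(
    records: Sequence[WomanRecord], config: Optional[CohortConfig] = None
) -> list[dict]:
    """Realised margins of a cohort, side by side with configured expectations.

    One row per SSA criterion plus rows for totals (SSA/WHO severe maternal
    outcomes, deaths, transfused women).  ``expected`` is ``None`` when no
    configuration is supplied.
    """
    from .classify import classify_cohort
    from .criteria import CATALOG

    classifications = classify_cohort(records)
    expected = None
    if config is not None:
        intercept = (
            config.death_intercept
            if config.death_intercept is not None
            else calibrate_death_intercept(config)
        )
        expected = expected_margins(config, death_intercept=intercept)

    rows = []
    for crit in (c for c in CATALOG if c.in_ssa):
        realized = sum(crit.key in cl.ssa_fired for cl in classifications)
        exp = expected["criterion_expected"].get(crit.key, 0.0) if expected else None
        rows.append({"margin": crit.key, "realized": realized, "expected": exp})
    totals = {
        "ssa_smo": sum(cl.smo_ssa for cl in classifications),
        "who_smo": sum(cl.smo_who for cl in classifications),
        "deaths": sum(cl.outcome == "maternal_death" for cl in classifications),
        "transfused": sum(r.transfusion_units >= 1 for r in records),
    }
    for name, realized in totals.items():
        rows.append(
            {
                "margin": name,
                "realized": realized,
                "expected": expected[name] if expected else None,
            }
        )
    return rows
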