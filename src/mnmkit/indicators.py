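"""Severe-maternal-outcome indicator panel, cause breakdown, process indicators.

The near-miss indicator panel summarises a facility cohort against its live
births denominator:

* SMO ratio      = 1000 * (MNM + MD) / live births
* MNM ratio      = 1000 * MNM / live births
* MNM:MD ratio   = MNM / MD  (near-miss survivors per maternal death)
* Mortality index (MI) = 100 * MD / (MNM + MD); lower MI indicates better
  quality of care for women who reach a life-threatening state.

Hospital-access indicators split SMO cases into those whose organ dysfunction
or death was present on arrival or within 12 hours of admission (SM012) and
the intrahospital remainder, each with its own mortality index.

All stored values keep full precision; rounding to the conventional one
decimal happens only in the formatted output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .classify import Classification
from .criteria import DEFAULT_CONFIG, EngineConfig
from .records import WomanRecord

__all__ = [
    "IndicatorPanel",
    "CauseBreakdown",
    "CauseRow",
    "ProcessIndicatorReport",
    "SweepRow",
    "CAUSE_GROUPS",
    "compute_panel",
    "panel_from_counts",
    "cause_breakdown",
    "process_indicators",
    "transfusion_threshold_sweep",
]

#: underlying-cause groups used in the cause-specific breakdown
CAUSE_GROUPS: dict[str, tuple[str, ...]] = {
    "hypertensive_disorders": ("severe_preeclampsia", "eclampsia_cause"),
    "obstetric_hemorrhage": (
        "abortion_related",
        "ectopic_pregnancy",
        "abruptio_placenta",
        "placenta_previa",
        "uterine_rupture_cause",
        "severe_pph",
        "other_hemorrhage",
    ),
    "sepsis_severe_infection": ("sepsis_cause",),
    "other": ("other", "none"),
}


def _ratio(n: int, d: int, scale: float) -> Optional[float]:
    return scale * n / d if d else None


@dataclass(frozen=True)
class IndicatorPanel:
    """The overall, hospital-access and intrahospital near-miss indicators."""

    tool: str
    live_births: int
    smo: int
    mnm: int
    md: int
    smo_ratio: Optional[float]            # per 1000 live births
    mnm_ratio: Optional[float]            # per 1000 live births
    mnm_md_ratio: Optional[float]         # MNM per maternal death
    mortality_index_pct: Optional[float]  # None when SMO == 0 (undefined)
    sm012: int
    sm012_prop_pct: Optional[float]
    sm012_referred_prop_pct: Optional[float]
    sm012_mortality_index_pct: Optional[float]
    intrahospital_smo: int
    intrahospital_rate: Optional[float]   # per 1000 live births
    intrahospital_mortality_index_pct: Optional[float]

    def to_dict(self, ndigits: Optional[int] = 1) -> dict:
        """Plain-dict form; floats rounded to ``ndigits`` unless ``None``."""

        def r(x):
            if x is None or ndigits is None:
                return x
            return round(x, ndigits)

        return {
            "tool": self.tool,
            "live_births": self.live_births,
            "smo": self.smo,
            "mnm": self.mnm,
            "md": self.md,
            "smo_ratio": r(self.smo_ratio),
            "mnm_ratio": r(self.mnm_ratio),
            "mnm_md_ratio": r(self.mnm_md_ratio),
            "mortality_index_pct": r(self.mortality_index_pct),
            "sm012": self.sm012,
            "sm012_prop_pct": r(self.sm012_prop_pct),
            "sm012_referred_prop_pct": r(self.sm012_referred_prop_pct),
            "sm012_mortality_index_pct": r(self.sm012_mortality_index_pct),
            "intrahospital_smo": self.intrahospital_smo,
            "intrahospital_rate": r(self.intrahospital_rate),
            "intrahospital_mortality_index_pct": r(self.intrahospital_mortality_index_pct),
        }


def panel_from_counts(
    *,
    tool: str,
    mnm: int,
    md: int,
    live_births: int,
    sm012: int = 0,
    sm012_deaths: int = 0,
    sm012_referred: int = 0,
) -> IndicatorPanel:
    """Build the indicator panel directly from aggregate counts.

    This is the arithmetic core shared by :func:`compute_panel`; it also lets
    published aggregate counts be re-expressed as the full indicator panel
    without patient-level data.
    """
    if live_births <= 0:
        raise ValueError("live_births must be positive")
    if min(mnm, md, sm012, sm012_deaths, sm012_referred) < 0:
        raise ValueError("counts must be non-negative")
    smo = mnm + md
    if sm012 > smo:
        raise ValueError("sm012 cannot exceed total SMO")
    intra = smo - sm012
    intra_deaths = md - sm012_deaths
    return IndicatorPanel(
        tool=tool,
        live_births=live_births,
        smo=smo,
        mnm=mnm,
        md=md,
        smo_ratio=_ratio(smo, live_births, 1000),
        mnm_ratio=_ratio(mnm, live_births, 1000),
        mnm_md_ratio=_ratio(mnm, md, 1) if md else None,
        mortality_index_pct=_ratio(md, smo, 100),
        sm012=sm012,
        sm012_prop_pct=_ratio(sm012, smo, 100),
        sm012_referred_prop_pct=_ratio(sm012_referred, sm012, 100),
        sm012_mortality_index_pct=_ratio(sm012_deaths, sm012, 100),
        intrahospital_smo=intra,
        intrahospital_rate=_ratio(intra, live_births, 1000),
        intrahospital_mortality_index_pct=_ratio(intra_deaths, intra, 100),
    )


def compute_panel(
    classifications: Sequence[Classification], live_births: int, tool: str
) -> IndicatorPanel:
    """Compute the indicator panel for one tool from per-woman classifications."""
    if tool not in ("who", "ssa"):
        raise ValueError(f"unknown tool {tool!r}")
    smo = [c for c in classifications if getattr(c, f"smo_{tool}")]
    mnm = sum(getattr(c, f"{tool}_status") == "mnm" for c in smo)
    md = sum(getattr(c, f"{tool}_status") == "maternal_death" for c in smo)
    sm012_cases = [c for c in smo if c.dysfunction_within_12h]
    return panel_from_counts(
        tool=tool,
        mnm=mnm,
        md=md,
        live_births=live_births,
        sm012=len(sm012_cases),
        sm012_deaths=sum(
            getattr(c, f"{tool}_status") == "maternal_death" for c in sm012_cases
        ),
        sm012_referred=sum(c.referred for c in sm012_cases),
    )


# ---------------------------------------------------------------------------
# cause-specific breakdown
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CauseRow:
    """MNM / MD counts and mortality index for one underlying-cause group or
    member cause.  Percentages are shares of the tool's total MNM and MD."""

    name: str
    group: str
    mnm: int
    mnm_pct: Optional[float]
    md: int
    md_pct: Optional[float]
    mortality_index_pct: Optional[float]


@dataclass(frozen=True)
class CauseBreakdown:
    tool: str
    total_mnm: int
    total_md: int
    rows: tuple[CauseRow, ...]
    contributory: dict  # factor -> {"mnm": n, "md": n}
    critical_interventions: dict  # intervention -> {"mnm": n, "md": n}
    warnings: tuple[str, ...] = ()


def cause_breakdown(
    classifications: Sequence[Classification],
    records: Sequence[WomanRecord],
    tool: str,
) -> CauseBreakdown:
    """Underlying causes, contributory factors and critical interventions
    among the SMO cases of one tool.

    The mortality index of each cause group uses MD / (MD + MNM) within the
    group.  SMO cases with no documented underlying cause are counted in the
    ``other`` group with a warning.
    """
    by_id = {r.id: r for r in records}
    member_group = {m: g for g, members in CAUSE_GROUPS.items() for m in members}
    warnings: list[str] = []

    counts: dict[str, list[int]] = {}  # cause/group name -> [mnm, md]

    def bump(name: str, is_death: bool) -> None:
        c = counts.setdefault(name, [0, 0])
        c[1 if is_death else 0] += 1

    total_mnm = total_md = 0
    for cl in classifications:
        if not getattr(cl, f"smo_{tool}"):
            continue
        record = by_id[cl.id]
        is_death = getattr(cl, f"{tool}_status") == "maternal_death"
        total_md += is_death
        total_mnm += not is_death
        cause = record.underlying_cause
        if cause == "none":
            warnings.append(f"{cl.id}: SMO case with no underlying cause; counted as other")
        group = member_group.get(cause, "other")
        bump(group, is_death)
        if group != "other":
            bump(cause, is_death)
        intervened = {
            "blood_transfusion": record.transfusion_units >= 1,
            "icu_admission": record.icu_admission,
            "cesarean_section": record.mode_of_delivery == "cesarean_section",
            "laparotomy_other_than_cs": record.laparotomy_other_than_cs,
        }
        for name, hit in intervened.items():
            if hit:
                bump(f"ci:{name}", is_death)
        if record.anemia:
            bump("cf:anemia", is_death)
        if record.previous_cesarean:
            bump("cf:previous_cesarean", is_death)

    def row(name: str, group: str) -> CauseRow:
        mnm, md = counts.get(name, [0, 0])
        return CauseRow(
            name=name,
            group=group,
            mnm=mnm,
            mnm_pct=_ratio(mnm, total_mnm, 100),
            md=md,
            md_pct=_ratio(md, total_md, 100),
            mortality_index_pct=_ratio(md, mnm + md, 100),
        )

    rows: list[CauseRow] = []
    for group, members in CAUSE_GROUPS.items():
        rows.append(row(group, group))
        if group != "other":
            for m in members:
                rows.append(row(m, group))

    def pair(name: str) -> dict:
        mnm, md = counts.get(name, [0, 0])
        return {"mnm": mnm, "md": md}

    return CauseBreakdown(
        tool=tool,
        total_mnm=total_mnm,
        total_md=total_md,
        rows=tuple(rows),
        contributory={
            "anemia": pair("cf:anemia"),
            "previous_cesarean": pair("cf:previous_cesarean"),
        },
        critical_interventions={
            "blood_transfusion": pair("ci:blood_transfusion"),
            "icu_admission": pair("ci:icu_admission"),
            "cesarean_section": pair("ci:cesarean_section"),
            "laparotomy_other_than_cs": pair("ci:laparotomy_other_than_cs"),
        },
        warnings=tuple(warnings),
    )


# ---------------------------------------------------------------------------
# process indicators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProcessIndicatorReport:
    """Coverage of recommended interventions per condition-specific target
    population, over the whole enrolled cohort (not only SMO cases).

    ``populations`` maps population name -> {"denominator": n, "items":
    {item: {"n": numerator, "pct": coverage or None}}}.  The SMO proportion
    item follows the original WHO tool's classification.  Indicators over an
    empty target population are reported as undefined (``pct`` None).
    """

    populations: dict


def _coverage(n: int, denom: int) -> dict:
    return {"n": n, "pct": _ratio(n, denom, 100)}


def process_indicators(
    records: Sequence[WomanRecord],
    classifications: Sequence[Classification],
) -> ProcessIndicatorReport:
    by_id = {c.id: c for c in classifications}

    def pop(selector) -> list[WomanRecord]:
        return [r for r in records if selector(r, by_id[r.id])]

    def report(members: list[WomanRecord], items: dict) -> dict:
        denom = len(members)
        out = {"denominator": denom, "items": {}}
        for label, pred in items.items():
            n = sum(1 for r in members if pred(r, by_id[r.id]))
            out["items"][label] = _coverage(n, denom)
        return out

    def smo_who(r, cl):
        return cl.smo_who

    def died(r, cl):
        return r.outcome == "maternal_death"

    populations = {
        "severe_pph": report(
            pop(lambda r, cl: r.underlying_cause == "severe_pph"),
            {
                "oxytocin": lambda r, cl: "oxytocin" in r.uterotonics_given,
                "ergometrine": lambda r, cl: "ergometrine" in r.uterotonics_given,
                "misoprostol": lambda r, cl: "misoprostol" in r.uterotonics_given,
                "other_uterotonics": lambda r, cl: "other" in r.uterotonics_given,
                "any_uterotonic": lambda r, cl: bool(r.uterotonics_given),
                "hysterectomy": lambda r, cl: r.hysterectomy_any,
                "smo_proportion": smo_who,
                "mortality": died,
            },
        ),
        "eclampsia": report(
            pop(lambda r, cl: "eclampsia" in cl.ssa_fired),
            {
                "magnesium_sulfate": lambda r, cl: r.magnesium_sulfate,
                "other_anticonvulsant": lambda r, cl: r.other_anticonvulsant,
                "any_anticonvulsant": lambda r, cl: r.magnesium_sulfate
                or r.other_anticonvulsant,
                "smo_proportion": smo_who,
                "mortality": died,
            },
        ),
        "cesarean_section": report(
            pop(lambda r, cl: r.mode_of_delivery == "cesarean_section"),
            {
                "prophylactic_antibiotic": lambda r, cl: r.prophylactic_antibiotic_at_cs,
            },
        ),
        "sepsis": report(
            pop(lambda r, cl: "sepsis_severe_infection" in cl.ssa_fired),
            {
                "parenteral_therapeutic_antibiotics": lambda r, cl: r.parenteral_therapeutic_antibiotics,
                "smo_proportion": smo_who,
                "mortality": died,
            },
        ),
        "ruptured_uterus": report(
            pop(lambda r, cl: "uterine_rupture" in cl.ssa_fired),
            {
                "hysterectomy": lambda r, cl: r.hysterectomy_any,
                "smo_proportion": smo_who,
                "mortality": died,
            },
        ),
    }
    return ProcessIndicatorReport(populations=populations)


# ---------------------------------------------------------------------------
# transfusion threshold sensitivity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepRow:
    """Sensitivity of inclusion to the transfusion threshold ``t``:
    how many women received >= t units, and how many of them fulfil no other
    criterion of the chosen tool (so inclusion hinges on the threshold)."""

    threshold: int
    n_fired: int
    n_sole_criterion: int


def transfusion_threshold_sweep(
    records: Sequence[WomanRecord],
    thresholds: Sequence[int],
    tool: str = "who",
    config: EngineConfig = DEFAULT_CONFIG,
) -> list[SweepRow]:
    """Count, for each candidate transfusion threshold, the women whose
    transfusion criterion would fire and those for whom it would be the only
    criterion of ``tool``."""
    if any(t < 1 for t in thresholds):
        raise ValueError("thresholds must be positive unit counts")
    # pre-compute whether any non-transfusion criterion of the tool fires
    from .criteria import CATALOG  # local to avoid cycle at import time

    members = [c for c in CATALOG if getattr(c, f"in_{tool}") and c.key != "transfusion"]
    other_fired = [
        any(c.predicate(r, tool, config) is not None for c in members) for r in records
    ]
    rows = []
    for t in thresholds:
        n_fired = sum(r.transfusion_units >= t for r in records)
        n_sole = sum(
            r.transfusion_units >= t and not other
            for r, other in zip(records, other_fired)
        )
        rows.append(SweepRow(threshold=t, n_fired=n_fired, n_sole_criterion=n_sole))
    return rows
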