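"""Two-step cohort classification and dual-tool discordance analysis.

Facility-based near-miss review proceeds in two steps: women admitted with a
potentially life-threatening condition (PLTC) are enrolled, and at discharge
each is classified under a near-miss tool as a maternal near miss (MNM,
survived with at least one criterion fulfilled), a maternal death (MD), or
neither.  MNM plus MD constitute the severe maternal outcomes (SMO).

Because this package runs the WHO and sub-Saharan Africa (SSA) tools side by
side over the same cohort, it also produces the per-criterion discordance
table: for each SSA criterion, how many of the women it captures fulfil no
criterion of the original WHO tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .criteria import CATALOG, DEFAULT_CONFIG, EngineConfig, fired_keys
from .records import WomanRecord

__all__ = [
    "Classification",
    "DiscordanceRow",
    "ClassifierConfig",
    "PLTC_CAUSES",
    "screen_pltc",
    "classify_record",
    "classify_cohort",
    "discordance_table",
    "ssa_only_attribution",
    "ATTRIBUTABLE_REASONS",
]

#: underlying complications that enrol a woman as PLTC by condition alone
PLTC_CAUSES = (
    "severe_pph",
    "severe_preeclampsia",
    "eclampsia_cause",
    "uterine_rupture_cause",
    "abortion_related",
    "sepsis_cause",
)

ATTRIBUTABLE_REASONS = ("eclampsia", "sepsis", "transfusion_threshold")


@dataclass(frozen=True)
class ClassifierConfig:
    """Cohort-classification behaviour.

    ``count_all_deaths``: when on, every maternal death is counted as an SMO
    under both tools regardless of whether any criterion is documented.  The
    default requires a fired criterion, so that deaths with insufficient chart
    documentation are counted under neither tool (they are reported with a
    warning instead of silently absorbed).
    ``pltc_causes`` is site-configurable screening data, not code.
    """

    count_all_deaths: bool = False
    pltc_causes: tuple[str, ...] = PLTC_CAUSES
    engine: EngineConfig = field(default_factory=EngineConfig)


DEFAULT_CLASSIFIER = ClassifierConfig()


@dataclass(frozen=True)
class Classification:
    """Per-woman verdict under both tools."""

    id: str
    pltc: bool
    who_status: str  # none | mnm | maternal_death
    ssa_status: str
    who_fired: tuple[str, ...]
    ssa_fired: tuple[str, ...]
    smo_who: bool
    smo_ssa: bool
    # carried from the record for indicator computation
    dysfunction_within_12h: bool = False
    referred: bool = False
    outcome: str = "discharged_alive"


@dataclass(frozen=True)
class DiscordanceRow:
    """One row of the per-criterion discordance table.

    ``n_ssa``: women for whom the criterion fired under the SSA tool.
    ``n_who``: of those, women fulfilling at least one WHO criterion.
    ``n_ssa_only_cases``: of those, women fulfilling no WHO criterion.
    For criteria shared by both tools the last column is structurally zero.
    """

    key: str
    label: str
    group: str
    n_ssa: int
    n_who: int
    n_ssa_only_cases: int


def screen_pltc(
    record: WomanRecord, config: ClassifierConfig = DEFAULT_CLASSIFIER
) -> bool:
    """PLTC enrolment screen: a listed life-threatening condition, a critical
    intervention (any blood products, laparotomy other than cesarean), or
    admission to the intensive care unit."""
    return (
        record.underlying_cause in config.pltc_causes
        or record.transfusion_units >= 1
        or record.laparotomy_other_than_cs
        or record.icu_admission
    )


def _status(record: WomanRecord, fired: Sequence[str], count_all_deaths: bool) -> str:
    if record.outcome == "maternal_death":
        if fired or count_all_deaths:
            return "maternal_death"
        return "none"
    return "mnm" if fired else "none"


def classify_record(
    record: WomanRecord, config: ClassifierConfig = DEFAULT_CLASSIFIER
) -> Classification:
    """Classify one woman under both tools."""
    who = tuple(fired_keys(record, "who", config.engine))
    ssa = tuple(fired_keys(record, "ssa", config.engine))
    who_status = _status(record, who, config.count_all_deaths)
    ssa_status = _status(record, ssa, config.count_all_deaths)
    return Classification(
        id=record.id,
        pltc=screen_pltc(record, config),
        who_status=who_status,
        ssa_status=ssa_status,
        who_fired=who,
        ssa_fired=ssa,
        smo_who=who_status != "none",
        smo_ssa=ssa_status != "none",
        dysfunction_within_12h=record.dysfunction_within_12h_of_admission,
        referred=record.referred_from_other_facility,
        outcome=record.outcome,
    )


def classify_cohort(
    records: Iterable[WomanRecord], config: ClassifierConfig = DEFAULT_CLASSIFIER
) -> list[Classification]:
    """Classify every woman in a cohort under both tools.

    Raises ``ValueError`` on duplicate identifiers.  Deaths fulfilling no
    criterion of a tool are classified ``none`` under that tool unless
    ``config.count_all_deaths`` is set (see :class:`ClassifierConfig`).
    """
    out: list[Classification] = []
    seen: set[str] = set()
    for record in records:
        if record.id in seen:
            raise ValueError(f"duplicate record id {record.id!r}")
        seen.add(record.id)
        out.append(classify_record(record, config))
    return out


def uncounted_deaths(classifications: Sequence[Classification]) -> dict[str, list[str]]:
    """Ids of maternal deaths not counted as SMO under each tool.

    Under the default criteria-required rule a death with no documented
    criterion is excluded from that tool's SMO; these are surfaced so the
    analyst can audit documentation gaps rather than lose them silently.
    """
    return {
        tool: [
            c.id
            for c in classifications
            if c.outcome == "maternal_death" and not getattr(c, f"smo_{tool}")
        ]
        for tool in ("who", "ssa")
    }


def discordance_table(
    classifications: Sequence[Classification],
) -> list[DiscordanceRow]:
    """Per-criterion distribution of cases under the SSA tool versus the WHO
    tool, with per-criterion counts of women fulfilling no WHO criterion.

    Criterion rows are non-exclusive (a woman firing several criteria is
    counted on each of their rows).  Aggregate rows cover any clinical, any
    laboratory and any management criterion, and totals for MNM, maternal
    deaths and SMO.
    """
    rows: list[DiscordanceRow] = []
    ssa_catalog = [c for c in CATALOG if c.in_ssa]

    def _count(pred) -> tuple[int, int, int]:
        n_ssa = n_who = n_only = 0
        for cl in classifications:
            if pred(cl):
                n_ssa += 1
                if cl.who_fired:
                    n_who += 1
                else:
                    n_only += 1
        return n_ssa, n_who, n_only

    for crit in ssa_catalog:
        n_ssa, n_who, n_only = _count(lambda cl, k=crit.key: k in cl.ssa_fired)
        rows.append(DiscordanceRow(crit.key, crit.label, crit.group, n_ssa, n_who, n_only))

    group_keys = {
        "clinical": [c.key for c in ssa_catalog if c.group == "clinical"],
        "laboratory": [c.key for c in ssa_catalog if c.group == "laboratory"],
        "management": [c.key for c in ssa_catalog if c.group == "management"],
    }
    for group, keys in group_keys.items():
        n_ssa, n_who, n_only = _count(
            lambda cl, ks=tuple(keys): any(k in cl.ssa_fired for k in ks)
        )
        rows.append(
            DiscordanceRow(f"any_{group}", f"Any {group} criteria", group, n_ssa, n_who, n_only)
        )

    n_mnm_ssa = sum(cl.ssa_status == "mnm" for cl in classifications)
    n_mnm_who = sum(cl.who_status == "mnm" for cl in classifications)
    n_md_ssa = sum(cl.ssa_status == "maternal_death" for cl in classifications)
    n_md_who = sum(cl.who_status == "maternal_death" for cl in classifications)
    n_smo_ssa = sum(cl.smo_ssa for cl in classifications)
    n_smo_who = sum(cl.smo_who for cl in classifications)
    rows.append(
        DiscordanceRow(
            "total_mnm",
            "Maternal near miss",
            "total",
            n_mnm_ssa,
            n_mnm_who,
            sum(cl.ssa_status == "mnm" and not cl.smo_who for cl in classifications),
        )
    )
    rows.append(
        DiscordanceRow(
            "total_md",
            "Maternal deaths",
            "total",
            n_md_ssa,
            n_md_who,
            sum(
                cl.ssa_status == "maternal_death" and not cl.smo_who
                for cl in classifications
            ),
        )
    )
    rows.append(
        DiscordanceRow(
            "total_smo",
            "Total severe maternal outcome",
            "total",
            n_smo_ssa,
            n_smo_who,
            sum(cl.smo_ssa and not cl.smo_who for cl in classifications),
        )
    )
    return rows


def ssa_only_attribution(classification: Classification) -> tuple[str, ...]:
    """Reasons an SSA-only SMO case escaped the WHO tool.

    For a woman who is SMO under the SSA tool but not under the WHO tool,
    returns which of the three headline sources of discordance apply:
    the eclampsia criterion, the sepsis criterion, or the lower transfusion
    threshold (2-4 units fire the SSA criterion but not the WHO one).
    Empty for concordant women or discordance from other SSA-only criteria.
    """
    if not (classification.smo_ssa and not classification.smo_who):
        return ()
    reasons = []
    if "eclampsia" in classification.ssa_fired:
        reasons.append("eclampsia")
    if "sepsis_severe_infection" in classification.ssa_fired:
        reasons.append("sepsis")
    if "transfusion" in classification.ssa_fired and "transfusion" not in classification.who_fired:
        reasons.append("transfusion_threshold")
    return tuple(reasons)
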