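"""Report rendering: classification, discordance and indicator tables as
DataFrames, CSV and aligned plain text.

Percentages and ratios are rounded to one decimal in rendered output; the
underlying objects keep full precision.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .classify import Classification, DiscordanceRow
from .indicators import (
    CauseBreakdown,
    IndicatorPanel,
    ProcessIndicatorReport,
    SweepRow,
)

__all__ = [
    "classifications_to_frame",
    "discordance_to_frame",
    "panel_to_frame",
    "cause_breakdown_to_frame",
    "process_report_to_frame",
    "sweep_to_frame",
    "render_text",
]


def _r1(x: Optional[float]) -> Optional[float]:
    return None if x is None else round(x, 1)


def classifications_to_frame(classifications: Sequence[Classification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [c.id for c in classifications],
            "pltc": [c.pltc for c in classifications],
            "who_status": [c.who_status for c in classifications],
            "ssa_status": [c.ssa_status for c in classifications],
            "smo_who": [c.smo_who for c in classifications],
            "smo_ssa": [c.smo_ssa for c in classifications],
            "who_fired": [";".join(c.who_fired) for c in classifications],
            "ssa_fired": [";".join(c.ssa_fired) for c in classifications],
            "dysfunction_within_12h": [c.dysfunction_within_12h for c in classifications],
            "referred": [c.referred for c in classifications],
            "outcome": [c.outcome for c in classifications],
        }
    )


def discordance_to_frame(rows: Sequence[DiscordanceRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "criterion": [r.key for r in rows],
            "label": [r.label for r in rows],
            "group": [r.group for r in rows],
            "n_ssa": [r.n_ssa for r in rows],
            "n_who": [r.n_who for r in rows],
            "cases_not_fulfilling_who": [r.n_ssa_only_cases for r in rows],
        }
    )


def panel_to_frame(panels: Sequence[IndicatorPanel]) -> pd.DataFrame:
    """One column per tool, mirroring the conventional indicator-panel layout."""
    frames = {}
    for p in panels:
        d = p.to_dict(ndigits=1)
        tool = d.pop("tool")
        frames[tool] = pd.Series(d)
    out = pd.DataFrame(frames)
    out.index.name = "indicator"
    return out


def cause_breakdown_to_frame(cb: CauseBreakdown) -> pd.DataFrame:
    rows = []
    for r in cb.rows:
        rows.append(
            {
                "cause": r.name,
                "group": r.group,
                "mnm": r.mnm,
                "mnm_pct": _r1(r.mnm_pct),
                "md": r.md,
                "md_pct": _r1(r.md_pct),
                "mortality_index_pct": _r1(r.mortality_index_pct),
            }
        )
    for section, data in (
        ("contributory", cb.contributory),
        ("critical_intervention", cb.critical_interventions),
    ):
        for name, pair in data.items():
            rows.append(
                {
                    "cause": name,
                    "group": section,
                    "mnm": pair["mnm"],
                    "mnm_pct": _r1(100 * pair["mnm"] / cb.total_mnm) if cb.total_mnm else None,
                    "md": pair["md"],
                    "md_pct": _r1(100 * pair["md"] / cb.total_md) if cb.total_md else None,
                    "mortality_index_pct": None,
                }
            )
    return pd.DataFrame(rows)


def process_report_to_frame(report: ProcessIndicatorReport) -> pd.DataFrame:
    rows = []
    for pop, data in report.populations.items():
        for item, cov in data["items"].items():
            rows.append(
                {
                    "target_population": pop,
                    "denominator": data["denominator"],
                    "indicator": item,
                    "n": cov["n"],
                    "pct": _r1(cov["pct"]),
                }
            )
    return pd.DataFrame(rows)


def sweep_to_frame(rows: Sequence[SweepRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "threshold_units": [r.threshold for r in rows],
            "n_fired": [r.n_fired for r in rows],
            "n_sole_criterion": [r.n_sole_criterion for r in rows],
        }
    )


def render_text(frame: pd.DataFrame, title: str) -> str:
    """Aligned plain-text rendering of a report table."""
    body = frame.to_string(index=frame.index.name is not None, na_rep="-")
    rule = "=" * max(len(title), 8)
    return f"{title}\n{rule}\n{body}\n"
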