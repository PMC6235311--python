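"""Tabular input/output: the one-row-per-woman CSV dialect and report writers.

The cohort file is UTF-8 CSV with one row per woman and header names exactly
matching the :class:`~mnmkit.records.WomanRecord` field names.  Set-valued
fields (uterotonics) are semicolon-delimited tokens; missing values are empty
cells, and for booleans an empty cell means "not documented" for optional
flags (``antenatal_care``) and ``false`` for adjudicated signs.  Creatinine
may alternatively be supplied in mg/dl via a ``creatinine_mg_dl`` column and
is converted (x 88.4).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .records import (
    CREATININE_MGDL_TO_UMOL,
    WomanRecord,
    record_field_names,
)

__all__ = [
    "records_to_frame",
    "frame_to_records",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_data_dictionary",
]

_BOOL_FIELDS = {
    f.name
    for f in dataclasses.fields(WomanRecord)
    if f.type in ("bool", bool)
}
_OPTIONAL_BOOL_FIELDS = {"antenatal_care"}
_INT_FIELDS = {"age_years", "gestational_age_weeks", "parity", "transfusion_units",
               "proteinuria_dipstick"}
_SET_FIELDS = {"uterotonics_given"}


def _cell(value) -> object:
    if value is None:
        return ""
    if isinstance(value, frozenset):
        return ";".join(sorted(value))
    if isinstance(value, bool):
        return "true" if value else "false"
    return value


def records_to_frame(records: Sequence[WomanRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame in the canonical column order."""
    cols = record_field_names()
    data = {c: [_cell(getattr(r, c)) for r in records] for c in cols}
    return pd.DataFrame(data, columns=cols)


def _parse_bool(raw: str, fname: str) -> Optional[bool]:
    token = str(raw).strip().lower()
    if token in ("", "na", "nan", "none"):
        return None if fname in _OPTIONAL_BOOL_FIELDS else False
    if token in ("true", "1", "yes", "y"):
        return True
    if token in ("false", "0", "no", "n"):
        return False
    raise ValueError(f"{fname}: cannot parse boolean from {raw!r}")


def frame_to_records(frame: pd.DataFrame) -> list[WomanRecord]:
    """Parse a cohort DataFrame back into records.

    Unknown columns raise; absent optional columns default.  The alternate
    ``creatinine_mg_dl`` column is converted to μmol/l.
    """
    frame = frame.copy()
    if "creatinine_mg_dl" in frame.columns:
        if "creatinine_umol_l" in frame.columns:
            raise ValueError("supply creatinine in only one unit column")
        frame["creatinine_umol_l"] = (
            pd.to_numeric(frame.pop("creatinine_mg_dl"), errors="coerce")
            * CREATININE_MGDL_TO_UMOL
        )
    known = set(record_field_names())
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        raise ValueError(f"unknown columns in cohort file: {unknown}")

    records = []
    for _, row in frame.iterrows():
        kw: dict = {}
        for fname in frame.columns:
            raw = row[fname]
            missing = pd.isna(raw) or (isinstance(raw, str) and raw.strip() == "")
            if fname in _SET_FIELDS:
                kw[fname] = frozenset() if missing else frozenset(
                    t.strip() for t in str(raw).split(";") if t.strip()
                )
            elif fname in _BOOL_FIELDS or fname in _OPTIONAL_BOOL_FIELDS:
                kw[fname] = _parse_bool("" if missing else raw, fname)
            elif fname in _INT_FIELDS:
                kw[fname] = None if missing else int(float(raw))
            elif fname in ("id", "mode_of_delivery", "fetal_outcome", "underlying_cause", "outcome"):
                if not missing:
                    kw[fname] = str(raw).strip()
                elif fname == "id":
                    kw[fname] = ""
            else:
                kw[fname] = None if missing else float(raw)
        if kw.get("transfusion_units") is None:
            kw["transfusion_units"] = 0
        records.append(WomanRecord(**kw))
    return records


def write_cohort_csv(records: Sequence[WomanRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path) -> list[WomanRecord]:
    return frame_to_records(pd.read_csv(path, dtype=str, keep_default_na=False))


_FIELD_DOCS = {
    "id": "pseudonymous woman identifier (unique within a cohort)",
    "transfusion_units": "units of blood products transfused (integer >= 0)",
    "underlying_cause": "underlying complication group of the admission",
    "dysfunction_within_12h_of_admission": (
        "organ dysfunction or death present on arrival or within 12 h (SM012)"
    ),
    "outcome": "vital status at discharge",
}


def write_data_dictionary(path) -> None:
    """Emit the YAML data dictionary for the cohort CSV dialect."""
    entries = []
    for f in dataclasses.fields(WomanRecord):
        kind = (
            "set(semicolon-delimited)"
            if f.name in _SET_FIELDS
            else "bool"
            if f.name in _BOOL_FIELDS or f.name in _OPTIONAL_BOOL_FIELDS
            else "int"
            if f.name in _INT_FIELDS
            else "str"
            if f.name in ("id", "mode_of_delivery", "fetal_outcome", "underlying_cause", "outcome")
            else "float"
        )
        entries.append(
            {
                "field": f.name,
                "type": kind,
                "missing": "empty cell",
                "notes": _FIELD_DOCS.get(f.name, ""),
            }
        )
    Path(path).write_text(yaml.safe_dump(entries, sort_keys=False), encoding="utf-8")
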