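"""Shared fixtures: record factories and a small classified cohort."""

from __future__ import annotations

import pytest

from mnmkit.records import WomanRecord


@pytest.fixture
def make_record():
    """Factory for a minimal consistent record with field overrides."""

    counter = {"n": 0}

    def _make(**overrides) -> WomanRecord:
        counter["n"] += 1
        kw = {
            "id": overrides.pop("id", f"t{counter['n']:03d}"),
            "age_years": 26,
            "mode_of_delivery": "vaginal",
            "fetal_outcome": "alive",
        }
        kw.update(overrides)
        return WomanRecord(**kw)

    return _make


@pytest.fixture
def empty_record(make_record):
    """A woman with no signs, no labs, no interventions."""
    return make_record(id="empty")
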