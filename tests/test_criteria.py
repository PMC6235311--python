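"""Criteria-engine behaviour: catalogue structure, thresholds, predicates,
and an exhaustive comparison against an independent truth table."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnmkit.criteria import (
    CATALOG,
    EngineConfig,
    any_fired,
    evaluate,
    fired_keys,
    shared_keys,
    ssa_only_keys,
    who_only_keys,
)
from mnmkit.records import WomanRecord


class TestCatalogueStructure:
    def test_tool_membership_counts(self):
        assert sum(c.in_who for c in CATALOG) == 25
        assert sum(c.in_ssa for c in CATALOG) == 27
        assert len(shared_keys()) == 19

    def test_who_only_members(self):
        assert sorted(who_only_keys()) == sorted(
            ["pao2_fio2_low", "bilirubin_high", "ph_low", "lactate_high",
             "vasoactive_drugs", "dialysis"]
        )

    def test_ssa_only_members(self):
        assert sorted(ssa_only_keys()) == sorted(
            ["eclampsia", "uterine_rupture", "sepsis_severe_infection",
             "pulmonary_edema", "severe_abortion_complication", "severe_malaria",
             "severe_preeclampsia_icu", "laparotomy_other_than_cs"]
        )

    def test_unique_keys_and_groups(self):
        keys = [c.key for c in CATALOG]
        assert len(keys) == len(set(keys))
        assert {c.group for c in CATALOG} == {"clinical", "laboratory", "management"}


class TestPredicates:
    def test_empty_record_fires_nothing(self, empty_record):
        assert not any_fired(empty_record, "who")
        assert not any_fired(empty_record, "ssa")
        assert all(not r.fired for r in evaluate(empty_record, "who"))

    def test_eclampsia_only_fires_ssa_not_who(self, make_record):
        record = make_record(eclampsia=True, convulsion=True)
        assert fired_keys(record, "ssa") == ["eclampsia"]
        assert fired_keys(record, "who") == []

    @pytest.mark.parametrize(
        "units, who_fires, ssa_fires",
        [(0, False, False), (1, False, False), (2, False, True),
         (4, False, True), (5, True, True), (9, True, True)],
    )
    def test_transfusion_thresholds(self, make_record, units, who_fires, ssa_fires):
        record = make_record(transfusion_units=units)
        assert ("transfusion" in fired_keys(record, "who")) is who_fires
        assert ("transfusion" in fired_keys(record, "ssa")) is ssa_fires

    def test_transfusion_threshold_override(self, make_record):
        config = EngineConfig(who_transfusion_threshold=3)
        record = make_record(transfusion_units=3)
        assert "transfusion" in fired_keys(record, "who", config)

    def test_severe_preeclampsia_icu_requires_both(self, make_record):
        partial = make_record(severe_preeclampsia_flag=True)
        assert "severe_preeclampsia_icu" not in fired_keys(partial, "ssa")
        both = make_record(severe_preeclampsia_flag=True, icu_admission=True)
        assert "severe_preeclampsia_icu" in fired_keys(both, "ssa")
        assert "severe_preeclampsia_icu" not in fired_keys(both, "who")

    @pytest.mark.parametrize(
        "field, value, key, fires",
        [
            ("respiratory_rate", 41, "respiratory_rate_abnormal", True),
            ("respiratory_rate", 40, "respiratory_rate_abnormal", False),
            ("respiratory_rate", 5, "respiratory_rate_abnormal", True),
            ("respiratory_rate", 6, "respiratory_rate_abnormal", False),
            ("creatinine_umol_l", 300, "creatinine_high", True),
            ("creatinine_umol_l", 299, "creatinine_high", False),
            ("bilirubin_umol_l", 101, "bilirubin_high", True),
            ("bilirubin_umol_l", 100, "bilirubin_high", False),
            ("ph", 7.05, "ph_low", True),
            ("ph", 7.1, "ph_low", False),
            ("lactate_meq_ml", 5.5, "lactate_high", True),
            ("lactate_meq_ml", 5.0, "lactate_high", False),
            ("platelets_per_ml", 49999, "thrombocytopenia", True),
            ("platelets_per_ml", 50000, "thrombocytopenia", False),
            ("pao2_fio2_mmhg", 199, "pao2_fio2_low", True),
            ("pao2_fio2_mmhg", 200, "pao2_fio2_low", False),
        ],
    )
    def test_numeric_thresholds_as_printed(self, make_record, field, value, key, fires):
        record = make_record(**{field: value})
        assert (key in fired_keys(record, "who")) is fires

    def test_oxygen_saturation_needs_low_value_and_long_duration(self, make_record):
        ok = make_record(oxygen_saturation_pct=85, oxygen_saturation_duration_min=90)
        brief = make_record(oxygen_saturation_pct=85, oxygen_saturation_duration_min=30)
        high = make_record(oxygen_saturation_pct=93, oxygen_saturation_duration_min=90)
        assert "oxygen_saturation_low" in fired_keys(ok, "who")
        assert "oxygen_saturation_low" not in fired_keys(brief, "who")
        assert "oxygen_saturation_low" not in fired_keys(high, "who")

    def test_sepsis_from_raw_vitals_requires_three_signs(self, make_record):
        three = make_record(
            infection_sign=True, temperature_c=38.5, pulse_bpm=110, respiratory_rate=24
        )
        two = make_record(infection_sign=True, temperature_c=38.5, pulse_bpm=110)
        no_sign = make_record(temperature_c=38.5, pulse_bpm=110, respiratory_rate=24)
        assert "sepsis_severe_infection" in fired_keys(three, "ssa")
        assert "sepsis_severe_infection" not in fired_keys(two, "ssa")
        assert "sepsis_severe_infection" not in fired_keys(no_sign, "ssa")

    def test_sepsis_adjudicated_flag_suffices(self, make_record):
        record = make_record(sepsis_severe_infection=True, infection_sign=True)
        assert "sepsis_severe_infection" in fired_keys(record, "ssa")

    def test_eclampsia_computed_definition(self, make_record):
        fires = make_record(diastolic_bp_mmhg=95, convulsion=True)
        fires2 = make_record(proteinuria_dipstick=3, coma=True)
        hypertension_only = make_record(diastolic_bp_mmhg=95)
        convulsion_only = make_record(convulsion=True)
        assert "eclampsia" in fired_keys(fires, "ssa")
        assert "eclampsia" in fired_keys(fires2, "ssa")
        assert "eclampsia" not in fired_keys(hypertension_only, "ssa")
        assert "eclampsia" not in fired_keys(convulsion_only, "ssa")
        relaxed = EngineConfig(eclampsia_strict=False)
        assert "eclampsia" not in fired_keys(fires, "ssa", relaxed)

    def test_fired_results_carry_evidence(self, make_record):
        record = make_record(shock=True, transfusion_units=3)
        for res in evaluate(record, "ssa"):
            if res.fired:
                assert res.evidence

    def test_unknown_tool_rejected(self, empty_record):
        with pytest.raises(ValueError):
            evaluate(empty_record, "whoo")


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

_record_strategy = st.builds(
    WomanRecord,
    id=st.just("h"),
    shock=st.booleans(),
    eclampsia=st.booleans(),
    uterine_rupture=st.booleans(),
    sepsis_severe_infection=st.booleans(),
    pulmonary_edema=st.booleans(),
    severe_preeclampsia_flag=st.booleans(),
    icu_admission=st.booleans(),
    cpr=st.booleans(),
    dialysis_acute_renal_failure=st.booleans(),
    continuous_vasoactive_drugs=st.booleans(),
    laparotomy_other_than_cs=st.booleans(),
    hysterectomy_for_infection_or_hemorrhage=st.booleans(),
    transfusion_units=st.integers(min_value=0, max_value=8),
    creatinine_umol_l=st.one_of(st.none(), st.floats(0, 600, allow_nan=False)),
    platelets_per_ml=st.one_of(st.none(), st.floats(1000, 400000, allow_nan=False)),
)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(record=_record_strategy)
def test_shared_criteria_agree_across_tools(record):
    """A criterion present in both tools fires identically under both."""
    shared = set(shared_keys()) - {"transfusion"}  # tool-specific threshold
    who = set(fired_keys(record, "who")) & shared
    ssa = set(fired_keys(record, "ssa")) & shared
    assert who == ssa


@settings(max_examples=200, deadline=None, derandomize=True)
@given(record=_record_strategy)
def test_who_positive_implies_ssa_positive_or_who_only_pattern(record):
    """A WHO-positive woman is SSA-positive unless she fires only
    WHO-exclusive criteria (including a 5-unit-threshold-only transfusion,
    which cannot happen since 5 units also exceeds the SSA threshold)."""
    if any_fired(record, "who"):
        who = set(fired_keys(record, "who"))
        assert any_fired(record, "ssa") or who <= set(who_only_keys())


@settings(max_examples=100, deadline=None, derandomize=True)
@given(units=st.integers(min_value=1, max_value=10), tool=st.sampled_from(["who", "ssa"]))
def test_transfusion_monotone_in_units(units, tool):
    lower = WomanRecord(id="a", transfusion_units=units)
    higher = WomanRecord(id="b", transfusion_units=units + 1)
    if any_fired(lower, tool):
        assert any_fired(higher, tool)


# ---------------------------------------------------------------------------
# exhaustive oracle over a reduced record space
# ---------------------------------------------------------------------------


def _oracle_fired(kw: dict, tool: str) -> set:
    """Independent truth table for the reduced record space, written directly
    from the printed criteria lists rather than via the engine."""
    fired = set()
    units = kw["transfusion_units"]
    if kw["shock"]:
        fired.add("shock")
    if kw["cpr"]:
        fired.add("cpr")
    if kw["hysterectomy_for_infection_or_hemorrhage"]:
        fired.add("hysterectomy_infection_hemorrhage")
    if kw["creatinine_umol_l"] is not None and kw["creatinine_umol_l"] >= 300:
        fired.add("creatinine_high")
    if tool == "who":
        if units >= 5:
            fired.add("transfusion")
        if kw["dialysis_acute_renal_failure"]:
            fired.add("dialysis")
        if kw["continuous_vasoactive_drugs"]:
            fired.add("vasoactive_drugs")
    else:
        if units >= 2:
            fired.add("transfusion")
        if kw["eclampsia"]:
            fired.add("eclampsia")
        if kw["uterine_rupture"]:
            fired.add("uterine_rupture")
        if kw["sepsis_severe_infection"]:
            fired.add("sepsis_severe_infection")
        if kw["pulmonary_edema"]:
            fired.add("pulmonary_edema")
        if kw["laparotomy_other_than_cs"]:
            fired.add("laparotomy_other_than_cs")
        if kw["severe_preeclampsia_flag"] and kw["icu_admission"]:
            fired.add("severe_preeclampsia_icu")
    return fired


def test_engine_matches_exhaustive_truth_table():
    """Enumerate every combination of a 12-field reduced record space and
    compare the engine against the independent truth table under both tools."""
    bool_fields = [
        "shock", "eclampsia", "uterine_rupture", "sepsis_severe_infection",
        "pulmonary_edema", "severe_preeclampsia_flag", "icu_admission", "cpr",
        "dialysis_acute_renal_failure", "continuous_vasoactive_drugs",
        "hysterectomy_for_infection_or_hemorrhage", "laparotomy_other_than_cs",
    ]
    checked = 0
    for bits in itertools.product([False, True], repeat=len(bool_fields)):
        for units in (0, 2, 5):
            for creat in (None, 350.0):
                kw = dict(zip(bool_fields, bits))
                kw["transfusion_units"] = units
                kw["creatinine_umol_l"] = creat
                record = WomanRecord(id="x", **kw)
                for tool in ("who", "ssa"):
                    got = set(fired_keys(record, tool))
                    assert got == _oracle_fired(kw, tool), (kw, tool)
                checked += 1
    assert checked == 2 ** 12 * 3 * 2
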