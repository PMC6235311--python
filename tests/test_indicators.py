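"""Indicator-panel arithmetic, cause breakdown, process indicators and the
transfusion-threshold sweep."""

from __future__ import annotations

import pytest

from mnmkit.classify import classify_cohort
from mnmkit.indicators import (
    cause_breakdown,
    compute_panel,
    panel_from_counts,
    process_indicators,
    transfusion_threshold_sweep,
)
from mnmkit.synthetic import default_config, generate


class TestPanelArithmetic:
    def test_ratios_follow_definitions(self):
        p = panel_from_counts(tool="ssa", mnm=100, md=10, live_births=2000)
        assert p.smo == 110
        assert p.smo_ratio == pytest.approx(55.0)
        assert p.mnm_ratio == pytest.approx(50.0)
        assert p.mnm_md_ratio == pytest.approx(10.0)
        assert p.mortality_index_pct == pytest.approx(100 * 10 / 110)

    def test_no_deaths_gives_zero_mortality_index(self):
        p = panel_from_counts(tool="ssa", mnm=10, md=0, live_births=1000)
        assert p.mortality_index_pct == 0.0
        assert p.mnm_md_ratio is None

    def test_empty_smo_mortality_index_undefined_not_zero(self):
        p = panel_from_counts(tool="who", mnm=0, md=0, live_births=1000)
        assert p.mortality_index_pct is None
        assert p.smo_ratio == 0.0

    def test_live_births_must_be_positive(self):
        with pytest.raises(ValueError):
            panel_from_counts(tool="ssa", mnm=1, md=0, live_births=0)

    def test_sm012_cannot_exceed_smo(self):
        with pytest.raises(ValueError):
            panel_from_counts(tool="ssa", mnm=1, md=0, live_births=10, sm012=5)

    def test_scale_equivariance(self):
        a = panel_from_counts(
            tool="ssa", mnm=120, md=8, live_births=5000, sm012=100,
            sm012_deaths=6, sm012_referred=70,
        )
        b = panel_from_counts(
            tool="ssa", mnm=240, md=16, live_births=10000, sm012=200,
            sm012_deaths=12, sm012_referred=140,
        )
        for f in (
            "smo_ratio", "mnm_ratio", "mnm_md_ratio", "mortality_index_pct",
            "sm012_prop_pct", "sm012_referred_prop_pct",
            "sm012_mortality_index_pct", "intrahospital_rate",
            "intrahospital_mortality_index_pct",
        ):
            assert getattr(a, f) == pytest.approx(getattr(b, f))

    def test_ratio_and_index_identity(self):
        """MNM:MD ratio times MI/100 equals the MNM share of SMO."""
        p = panel_from_counts(tool="ssa", mnm=594, md=28, live_births=7404)
        assert p.mnm_md_ratio * p.mortality_index_pct / 100 == pytest.approx(
            p.mnm / p.smo
        )

    def test_sm012_and_intrahospital_mi_average_to_overall(self):
        """The SM012 and intrahospital mortality indices, weighted by their
        case counts, recover the overall mortality index."""
        records = generate(default_config(seed=21))
        panel = compute_panel(classify_cohort(records), 7404, "ssa")
        weighted = (
            panel.sm012 * panel.sm012_mortality_index_pct
            + panel.intrahospital_smo * panel.intrahospital_mortality_index_pct
        ) / panel.smo
        assert weighted == pytest.approx(panel.mortality_index_pct)
        assert panel.sm012 + panel.intrahospital_smo == panel.smo

    def test_compute_panel_matches_classification_counts(self):
        records = generate(default_config(seed=22))
        cls = classify_cohort(records)
        panel = compute_panel(cls, 7404, "who")
        assert panel.mnm == sum(c.who_status == "mnm" for c in cls)
        assert panel.md == sum(c.who_status == "maternal_death" for c in cls)


class TestCauseBreakdown:
    def test_single_sepsis_mnm(self, make_record):
        records = [make_record(id="s", sepsis_severe_infection=True,
                               underlying_cause="sepsis_cause")]
        cb = cause_breakdown(classify_cohort(records), records, "ssa")
        row = {r.name: r for r in cb.rows}["sepsis_severe_infection"]
        assert (row.mnm, row.mnm_pct, row.mortality_index_pct) == (1, 100.0, 0.0)

    def test_group_totals_equal_member_sums(self):
        records = generate(default_config(seed=23))
        cb = cause_breakdown(classify_cohort(records), records, "ssa")
        rows = {r.name: r for r in cb.rows}
        from mnmkit.indicators import CAUSE_GROUPS

        for group, members in CAUSE_GROUPS.items():
            if group == "other":
                continue
            assert rows[group].mnm == sum(rows[m].mnm for m in members)
            assert rows[group].md == sum(rows[m].md for m in members)

    def test_group_mortality_index_formula(self, make_record):
        """MI = MD/(MD+MNM)*100 within a cause group."""
        records = []
        for i in range(126):
            records.append(make_record(id=f"m{i}", sepsis_severe_infection=True,
                                       underlying_cause="sepsis_cause"))
        for i in range(3):
            records.append(make_record(id=f"d{i}", sepsis_severe_infection=True,
                                       underlying_cause="sepsis_cause",
                                       outcome="maternal_death"))
        cb = cause_breakdown(classify_cohort(records), records, "ssa")
        row = {r.name: r for r in cb.rows}["sepsis_severe_infection"]
        assert row.mortality_index_pct == pytest.approx(100 * 3 / 129)

    def test_smo_without_cause_warned_and_counted_as_other(self, make_record):
        records = [make_record(id="u", shock=True, underlying_cause="none")]
        cb = cause_breakdown(classify_cohort(records), records, "ssa")
        assert {r.name: r for r in cb.rows}["other"].mnm == 1
        assert cb.warnings


class TestProcessIndicators:
    def test_coverage_from_hand_built_population(self, make_record):
        records = [
            make_record(id=f"e{i}", eclampsia=True, convulsion=True,
                        magnesium_sulfate=(i < 3))
            for i in range(4)
        ]
        report = process_indicators(records, classify_cohort(records))
        pop = report.populations["eclampsia"]
        assert pop["denominator"] == 4
        assert pop["items"]["magnesium_sulfate"] == {"n": 3, "pct": 75.0}

    def test_population_of_one_with_item_given(self, make_record):
        records = [make_record(id="r", uterine_rupture=True, hysterectomy_any=True)]
        report = process_indicators(records, classify_cohort(records))
        item = report.populations["ruptured_uterus"]["items"]["hysterectomy"]
        assert item == {"n": 1, "pct": 100.0}

    def test_empty_population_is_undefined(self, empty_record):
        report = process_indicators([empty_record], classify_cohort([empty_record]))
        pop = report.populations["severe_pph"]
        assert pop["denominator"] == 0
        assert all(v["pct"] is None for v in pop["items"].values())

    def test_smo_proportion_uses_who_classification(self, make_record):
        # eclampsia alone is SSA-positive but WHO-negative
        records = [
            make_record(id="a", eclampsia=True, convulsion=True),
            make_record(id="b", eclampsia=True, convulsion=True, shock=True),
        ]
        report = process_indicators(records, classify_cohort(records))
        item = report.populations["eclampsia"]["items"]["smo_proportion"]
        assert item == {"n": 1, "pct": 50.0}


class TestTransfusionSweep:
    def test_minimum_threshold_fires_every_transfused_woman(self, make_record):
        records = [make_record(id=f"t{i}", transfusion_units=u)
                   for i, u in enumerate([0, 1, 2, 3, 5])]
        rows = transfusion_threshold_sweep(records, [1])
        assert rows[0].n_fired == 4

    def test_sweep_is_monotone_nonincreasing(self):
        records = generate(default_config(seed=24))
        rows = transfusion_threshold_sweep(records, [1, 2, 3, 4, 5, 6], tool="who")
        fired = [r.n_fired for r in rows]
        sole = [r.n_sole_criterion for r in rows]
        assert fired == sorted(fired, reverse=True)
        assert sole == sorted(sole, reverse=True)

    def test_sole_criterion_excludes_other_who_positives(self, make_record):
        records = [
            make_record(id="only", transfusion_units=2),
            make_record(id="with_shock", transfusion_units=2, shock=True),
        ]
        row = transfusion_threshold_sweep(records, [2], tool="who")[0]
        assert (row.n_fired, row.n_sole_criterion) == (2, 1)

    def test_thresholds_must_be_positive(self, empty_record):
        with pytest.raises(ValueError):
            transfusion_threshold_sweep([empty_record], [0])
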