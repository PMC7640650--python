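"""Silent-mode aggregation: percentage arithmetic, report shape, oracles."""

from collections import Counter
from datetime import timedelta

import pytest

from aki_cds import (
    Cohort,
    Setting,
    SimulationConfig,
    StagingConfig,
    build_report,
    generate_cohort,
    percent,
    run_silent,
)
from aki_cds.cohort import Cell, format_report, report_to_dict
from conftest import T0, make_patient

C, H = Setting.COMMUNITY, Setting.HOSPITAL


class TestPercentArithmetic:
    @pytest.mark.parametrize(
        "count,total,expected",
        [
            (54, 81, 66.7), (14, 81, 17.3), (13, 81, 16.0), (36, 81, 44.4),
            (66, 81, 81.5), (15, 81, 18.5),
            (11, 21, 52.4), (15, 21, 71.4), (4, 21, 19.0), (3, 21, 14.3),
            (1, 3, 33.3), (2, 3, 66.7),
        ],
    )
    def test_half_away_from_zero_to_one_decimal(self, count, total, expected):
        assert percent(count, total) == expected

    def test_zero_total_is_undefined(self):
        assert percent(0, 0) is None

    @pytest.mark.parametrize(
        "count,total,cell",
        [(54, 81, "54 (66.7)"), (11, 21, "11 (52.4)"), (0, 0, "0 (—)")],
    )
    def test_cell_rendering(self, count, total, cell):
        assert str(Cell(count, percent(count, total))) == cell


def _stage_cohort(stage_values: dict[int, float], counts: dict[int, int]) -> Cohort:
    """A cohort engineered to produce exactly `counts[stage]` alerts per
    stage (one single-alert episode per patient)."""
    patients = []
    i = 0
    for stage, n in counts.items():
        for _ in range(n):
            i += 1
            patients.append(make_patient(
                pid=f"P{i:03d}",
                creatinine=[(T0 - timedelta(days=2), 100, C), (T0, stage_values[stage], H)],
            ))
    return Cohort(patients=patients)


STAGE_VALUES = {1: 160.0, 2: 210.0, 3: 310.0}


class TestRunSilent:
    def test_engineered_stage_counts_give_printed_percentages(self):
        cohort = _stage_cohort(STAGE_VALUES, {1: 54, 2: 14, 3: 13})
        alerts, warnings, report = run_silent(cohort)
        assert report.total_alerts == 81
        assert (report.alerts_by_stage[1].count, report.alerts_by_stage[1].pct) == (54, 66.7)
        assert (report.alerts_by_stage[2].count, report.alerts_by_stage[2].pct) == (14, 17.3)
        assert (report.alerts_by_stage[3].count, report.alerts_by_stage[3].pct) == (13, 16.0)

    def test_zero_alert_cohort_all_blank(self):
        cohort = _stage_cohort(STAGE_VALUES, {})
        alerts, warnings, report = run_silent(cohort)
        assert report.total_alerts == 0 and report.total_warnings == 0
        assert all(c.pct is None for c in report.alerts_by_stage.values())
        assert "0 (—)" in format_report(report)

    def test_single_stage2_alert(self):
        cohort = _stage_cohort(STAGE_VALUES, {2: 1})
        _, _, report = run_silent(cohort)
        assert report.alerts_by_stage[2].count == 1
        assert report.alerts_by_stage[2].pct == 100.0

    def test_totals_equal_list_lengths_and_partitions_sum(self, config, formulary):
        cohort, _ = generate_cohort(SimulationConfig(n_patients=200, seed=9, aki_incidence=0.4))
        alerts, warnings, report = run_silent(cohort, config, formulary)
        assert report.total_alerts == len(alerts)
        assert report.total_warnings == len(warnings)
        assert sum(c.count for c in report.alerts_by_stage.values()) == len(alerts)
        assert sum(c.count for c in report.alerts_by_unit_type.values()) == len(alerts)
        assert sum(c.count for c in report.warnings_by_stage.values()) == len(warnings)
        if report.total_alerts:
            assert sum(c.pct for c in report.alerts_by_stage.values()) == pytest.approx(
                100.0, abs=0.2
            )

    def test_with_meds_statistic_definition(self, config, formulary):
        cohort, _ = generate_cohort(SimulationConfig(n_patients=150, seed=2, aki_incidence=0.4))
        alerts, _, report = run_silent(cohort, config, formulary)
        expected = sum(1 for a in alerts if a.active_risk_medications)
        assert report.alerts_with_active_meds.count == expected

    def test_aggregation_matches_brute_force_recount(self, config, formulary):
        cohort, _ = generate_cohort(SimulationConfig(n_patients=150, seed=4, aki_incidence=0.4))
        alerts, warnings, report = run_silent(cohort, config, formulary)
        assert {s: c.count for s, c in report.alerts_by_stage.items()} == {
            s: Counter(a.stage for a in alerts)[s] for s in (1, 2, 3)
        }
        assert {s: c.count for s, c in report.warnings_by_stage.items()} == {
            s: Counter(w.aki_stage_at_order for w in warnings)[s] for s in (1, 2, 3)
        }
        class_counts = Counter()
        for a in alerts:
            for cls in {m.drug_class.value for m in a.active_risk_medications}:
                class_counts[cls] += 1
        assert {k: c.count for k, c in report.active_meds_by_class.items()} == {
            k: class_counts[k] for k in ("diuretic", "antibiotic", "acei_arb", "nsaid")
        }
        unit_counts = Counter(
            cohort.get(w.patient_id).encounter_at(w.raised_at).unit_type.value
            for w in warnings
        )
        assert {k: c.count for k, c in report.warnings_by_unit_type.items()} == {
            k: unit_counts[k] for k in ("medical", "surgical")
        }

    def test_report_json_round_trips_counts(self):
        cohort = _stage_cohort(STAGE_VALUES, {1: 2, 3: 1})
        _, _, report = run_silent(cohort)
        d = report_to_dict(report)
        assert d["total_alerts"] == 3
        assert d["alerts_by_stage"]["1"] == {"count": 2, "percent": 66.7}
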