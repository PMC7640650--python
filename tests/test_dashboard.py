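"""Dashboard aggregation: fluid arithmetic, panel contents, purity."""

from datetime import timedelta

import pytest

from aki_cds import (
    Analyte,
    FluidKind,
    FluidRecord,
    LabResult,
    MedicationOrder,
    Setting,
    acknowledge_alert,
    build_dashboard,
    detect,
    fluid_balance,
    urine_output_rate,
)
from aki_cds.dashboard import dashboard_to_dict, dashboard_to_html
from conftest import T0, make_patient

C, H = Setting.COMMUNITY, Setting.HOSPITAL


def _fluid(kind, volume, hours):
    return FluidRecord("P1", kind, volume, T0 + timedelta(hours=hours))


WINDOW = (T0, T0 + timedelta(hours=12))


class TestFluidArithmetic:
    def test_net_balance(self):
        fluids = [
            _fluid(FluidKind.INTAKE_IV, 1500, 1),
            _fluid(FluidKind.INTAKE_ORAL, 500, 2),
            _fluid(FluidKind.OUTPUT_URINE, 1200, 3),
        ]
        assert fluid_balance(fluids, WINDOW) == 800

    def test_outputs_only_negative(self):
        assert fluid_balance([_fluid(FluidKind.OUTPUT_URINE, 1500, 1)], WINDOW) == -1500

    def test_empty_interval_zero(self):
        assert fluid_balance([], WINDOW) == 0

    def test_interval_half_open(self):
        at_end = _fluid(FluidKind.INTAKE_IV, 100, 12)
        at_start = _fluid(FluidKind.INTAKE_IV, 50, 0)
        assert fluid_balance([at_start, at_end], WINDOW) == 50

    def test_urine_rate_with_weight(self):
        fluids = [_fluid(FluidKind.OUTPUT_URINE, 720, 3)]
        total, rate = urine_output_rate(fluids, WINDOW, weight_kg=60)
        assert total == 720
        assert rate == pytest.approx(1.0)

    def test_urine_rate_without_weight(self):
        total, rate = urine_output_rate([], WINDOW)
        assert total == 0 and rate is None

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            urine_output_rate([], WINDOW, weight_kg=0)

    def test_interval_additivity(self):
        fluids = [
            _fluid(FluidKind.INTAKE_IV, v, h)
            for v, h in [(300, 0.5), (400, 3), (250, 7), (100, 11.5)]
        ] + [_fluid(FluidKind.OUTPUT_URINE, 200, h) for h in (2, 6, 10)]
        whole = fluid_balance(fluids, WINDOW)
        parts = sum(
            fluid_balance(fluids, (T0 + timedelta(hours=h), T0 + timedelta(hours=h + 4)))
            for h in (0, 4, 8)
        )
        assert parts == whole


class TestBuildDashboard:
    def _patient(self):
        p = make_patient(
            creatinine=[
                (T0 - timedelta(days=2), 100, C),
                (T0, 160, H),
                (T0 + timedelta(hours=12), 150, H),
            ],
            orders=[MedicationOrder("P1", "ibuprofen", T0 - timedelta(days=1)),
                    MedicationOrder("P1", "vancomycin", T0 + timedelta(hours=1)),
                    MedicationOrder("P1", "digoxin", T0 + timedelta(hours=1))],
        )
        p.labs.append(LabResult("P1", Analyte.UREA, T0, 9.0))
        p.labs.append(LabResult("P1", Analyte.POTASSIUM, T0, 4.8))
        p.sort_events()
        return p

    def test_panel_counts(self, config, formulary):
        p = self._patient()
        alerts = detect(p, config, formulary).alerts
        s = build_dashboard(p, alerts, formulary, as_of=T0 + timedelta(days=1))
        assert len(s.alert_history) == 1
        assert len(s.creatinine_trend) == 3
        assert len(s.urea_trend) == 1
        assert [o.drug_name for o in s.meds_may_worsen_aki] == ["ibuprofen", "vancomycin"]
        assert s.electrolyte_trends["potassium"][0][1] == 4.8

    def test_dual_flag_drug_in_both_panels(self, config, formulary):
        p = self._patient()
        s = build_dashboard(p, [], formulary, as_of=T0 + timedelta(days=1))
        # vancomycin may cause AKI and is renally cleared
        assert "vancomycin" in [o.drug_name for o in s.meds_may_worsen_aki]
        assert "vancomycin" in [o.drug_name for o in s.meds_renally_cleared]
        assert "digoxin" in [o.drug_name for o in s.meds_renally_cleared]
        assert "digoxin" not in [o.drug_name for o in s.meds_may_worsen_aki]

    def test_acknowledged_alert_retained(self, config, formulary):
        p = self._patient()
        alerts = detect(p, config, formulary).alerts
        acked = [acknowledge_alert(a, a.raised_at + timedelta(hours=1)) for a in alerts]
        s = build_dashboard(p, acked, formulary, as_of=T0 + timedelta(days=1))
        assert len(s.alert_history) == 1
        assert s.alert_history[0].status.value == "acknowledged"

    def test_empty_patient_empty_panels(self, formulary):
        s = build_dashboard(make_patient(), [], formulary, as_of=T0)
        assert s.alert_history == [] and s.creatinine_trend == []
        assert s.urine_output_by_interval == [] or all(
            total == 0 for _, total in s.urine_output_by_interval
        )

    def test_pure_function_of_past_events(self, config, formulary):
        """Appending later events never changes an earlier dashboard."""
        p = self._patient()
        as_of = T0 + timedelta(hours=6)
        alerts = detect(p, config, formulary).alerts
        before = dashboard_to_dict(build_dashboard(p, alerts, formulary, as_of=as_of))
        p.labs.append(LabResult("P1", Analyte.CREATININE, T0 + timedelta(days=3), 400, setting=H))
        p.medication_orders.append(MedicationOrder("P1", "naproxen", T0 + timedelta(days=3)))
        p.sort_events()
        after = dashboard_to_dict(build_dashboard(p, alerts, formulary, as_of=as_of))
        assert before == after

    def test_html_render_self_contained(self, config, formulary):
        p = self._patient()
        alerts = detect(p, config, formulary).alerts
        html = dashboard_to_html(build_dashboard(p, alerts, formulary, as_of=T0 + timedelta(days=1)))
        assert html.startswith("<!DOCTYPE html>")
        assert "ibuprofen" in html and "AKI alert history" in html
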