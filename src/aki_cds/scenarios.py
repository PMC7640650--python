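"""Hand-built functional-testing scenarios.

Each scenario is a tiny event stream plus the exact alerts and
medication warnings the engine must produce for it. Together they cover
every alerting behavior the system implements: each stage reached via
the ratio criterion, stage 1 via the 48-h absolute rise, stage 3 via
the absolute value, all three baseline paths (7-day window, one-year
median, unavailable), progression, de-escalation, recovery with
re-alert, the medication-warning window boundaries, warnings without an
open episode, acknowledgment idempotence, community-result baselines,
and multi-class active-medication listing.

All timestamps hang off a fixed reference admission; expected outputs
were derived by hand from the staging rules and are asserted verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional

from .detection import (
    AlertStatus,
    StagingConfig,
    acknowledge_alert,
    detect,
)
from .medsafety import Formulary, generate_warnings
from .records import (
    Analyte,
    Cohort,
    Encounter,
    LabResult,
    MedicationOrder,
    Patient,
    Setting,
    UnitType,
    utc,
)

T = utc(2025, 3, 10, 8, 0)  # reference index time


@dataclass
class Scenario:
    name: str
    description: str
    patient: Patient
    #: (stage, episode_index) per expected alert, in order raised.
    expected_alerts: list[tuple[int, int]]
    #: (drug_name, aki_stage_at_order) per expected warning.
    expected_warnings: list[tuple[str, int]] = field(default_factory=list)
    #: drug names expected on the first alert's active-medication list.
    expected_first_alert_meds: Optional[list[str]] = None
    #: expected baseline method of the first alert's assessment.
    expected_baseline_method: Optional[str] = None
    #: run the acknowledgment idempotence check on the first alert.
    check_acknowledgment: bool = False


def _patient(
    pid: str,
    creatinine: list[tuple[datetime, float, Setting]],
    orders: list[MedicationOrder] = (),
    unit: UnitType = UnitType.MEDICAL,
) -> Patient:
    p = Patient(patient_id=pid)
    p.encounters.append(
        Encounter(f"E-{pid}", T - timedelta(hours=6), T + timedelta(days=7), unit, "Med-1")
    )
    for at, value, setting in creatinine:
        p.labs.append(LabResult(pid, Analyte.CREATININE, at, value, setting=setting))
    p.medication_orders = list(orders)
    p.sort_events()
    return p


def _h(hours: float) -> datetime:
    return T + timedelta(hours=hours)


def _d(days: float) -> datetime:
    return T - timedelta(days=days)


H, C = Setting.HOSPITAL, Setting.COMMUNITY


def fixture_scenarios() -> list[Scenario]:
    """The full named scenario suite (21 scenarios)."""
    s: list[Scenario] = []

    s.append(Scenario(
        "stage1_ratio",
        "Baseline 100 from a 2-day-old community result; index 160 gives "
        "ratio 1.6 → one stage-1 alert.",
        _patient("S01", [(_d(2), 100, C), (T, 160, H)]),
        expected_alerts=[(1, 1)],
        expected_baseline_method="short_window",
    ))
    s.append(Scenario(
        "stage2_ratio",
        "Baseline 100, index 210 → ratio 2.1 → a single stage-2 alert "
        "(the first alert of an episode may already be stage 2).",
        _patient("S02", [(_d(2), 100, C), (T, 210, H)]),
        expected_alerts=[(2, 1)],
    ))
    s.append(Scenario(
        "stage3_ratio",
        "Baseline 100, index 310 → ratio 3.1 → stage-3 alert.",
        _patient("S03", [(_d(2), 100, C), (T, 310, H)]),
        expected_alerts=[(3, 1)],
    ))
    s.append(Scenario(
        "stage1_absolute_rise_48h",
        "Ratio 230/195 = 1.18 is below 1.5, but the rise of 35 µmol/L over "
        "the 195 measured 24 h earlier exceeds 26.5 → stage 1 via the "
        "absolute 48-h criterion.",
        _patient("S04", [(_d(2), 200, C), (_h(-24), 195, H), (T, 230, H)]),
        expected_alerts=[(1, 1)],
    ))
    s.append(Scenario(
        "stage3_absolute_no_baseline",
        "No prior creatinine anywhere: baseline unavailable, but the index "
        "of 360 µmol/L is above the absolute stage-3 threshold of 353.6.",
        _patient("S05", [(T, 360, H)]),
        expected_alerts=[(3, 1)],
        expected_baseline_method="unavailable",
    ))
    s.append(Scenario(
        "stage3_absolute_with_high_baseline",
        "Baseline 300 gives ratio only 1.2, but 360 ≥ 353.6 → stage 3 via "
        "the absolute criterion despite the unremarkable ratio.",
        _patient("S06", [(_d(2), 300, C), (T, 360, H)]),
        expected_alerts=[(3, 1)],
    ))
    s.append(Scenario(
        "baseline_lowest_in_short_window",
        "Two results in the 7-day window (110 at t−3d, 90 at t−6d): the "
        "LOWEST (90) is the baseline, so 140/90 = 1.56 alerts; the most "
        "recent value (110) would not have.",
        _patient("S07", [(_d(3), 110, C), (_d(6), 90, C), (T, 140, H)]),
        expected_alerts=[(1, 1)],
        expected_baseline_method="short_window",
    ))
    s.append(Scenario(
        "baseline_year_median",
        "Nothing inside 7 days; results at t−100d (100), t−200d (80), "
        "t−300d (90) give a one-year median of 90 → 140/90 = 1.56 → stage 1.",
        _patient("S08", [(_d(100), 100, C), (_d(200), 80, C), (_d(300), 90, C), (T, 140, H)]),
        expected_alerts=[(1, 1)],
        expected_baseline_method="long_window_median",
    ))
    s.append(Scenario(
        "baseline_year_median_even_count",
        "Even count in the year window (100 at t−50d, 120 at t−200d): the "
        "median is the mean of the pair (110); 170/110 = 1.55 → stage 1.",
        _patient("S09", [(_d(50), 100, C), (_d(200), 120, C), (T, 170, H)]),
        expected_alerts=[(1, 1)],
        expected_baseline_method="long_window_median",
    ))
    s.append(Scenario(
        "baseline_unavailable_no_alert",
        "No history and an index of 150: no ratio, no 48-h rise, below the "
        "absolute threshold → no alert.",
        _patient("S10", [(T, 150, H)]),
        expected_alerts=[],
    ))
    s.append(Scenario(
        "progression_stage1_to_stage2",
        "160 then 210 against baseline 100: stage-1 alert followed by a "
        "stage-2 progression alert in the same episode.",
        _patient("S11", [(_d(2), 100, C), (T, 160, H), (_h(12), 210, H)]),
        expected_alerts=[(1, 1), (2, 1)],
    ))
    s.append(Scenario(
        "deescalation_no_alert",
        "After progressing to stage 2, a fall back to 160 (stage-1 range) "
        "raises nothing: only progression alerts within an episode.",
        _patient("S12", [(_d(2), 100, C), (T, 160, H), (_h(12), 210, H), (_h(24), 160, H)]),
        expected_alerts=[(1, 1), (2, 1)],
    ))
    s.append(Scenario(
        "recovery_then_realert",
        "Stage-1 alert at 160, recovery at 105 (full stage-0 assessment), "
        "then 170 qualifies again → a second alert in episode 2.",
        _patient("S13", [(_d(2), 100, C), (T, 160, H), (_h(12), 105, H), (_h(24), 170, H)]),
        expected_alerts=[(1, 1), (1, 2)],
    ))
    s.append(Scenario(
        "warning_inside_window",
        "Furosemide ordered 24 h after onset of a stage-1 episode → one "
        "interruptive warning carrying stage 1.",
        _patient("S14", [(_d(2), 100, C), (T, 160, H)],
                 orders=[MedicationOrder("S14", "furosemide", _h(24))]),
        expected_alerts=[(1, 1)],
        expected_warnings=[("furosemide", 1)],
    ))
    s.append(Scenario(
        "warning_at_window_boundary",
        "A risk order at exactly onset + 48 h still warns (the window is "
        "closed at both ends).",
        _patient("S15", [(_d(2), 100, C), (T, 160, H)],
                 orders=[MedicationOrder("S15", "ibuprofen", _h(48))]),
        expected_alerts=[(1, 1)],
        expected_warnings=[("ibuprofen", 1)],
    ))
    s.append(Scenario(
        "warning_outside_window_49h",
        "The same order one hour later (onset + 49 h), episode still open "
        "→ no warning.",
        _patient("S16", [(_d(2), 100, C), (T, 160, H)],
                 orders=[MedicationOrder("S16", "ibuprofen", _h(49))]),
        expected_alerts=[(1, 1)],
        expected_warnings=[],
    ))
    s.append(Scenario(
        "warning_no_open_episode",
        "NSAID ordered for a patient who never meets AKI criteria → no "
        "warning (and no alert).",
        _patient("S17", [(_d(2), 100, C), (T, 110, H)],
                 orders=[MedicationOrder("S17", "naproxen", _h(24))]),
        expected_alerts=[],
        expected_warnings=[],
    ))
    s.append(Scenario(
        "warning_after_recovery",
        "Diuretic ordered after the episode closed by recovery → no "
        "warning: 'patient with AKI' means an open episode.",
        _patient("S18", [(_d(2), 100, C), (T, 160, H), (_h(12), 105, H)],
                 orders=[MedicationOrder("S18", "furosemide", _h(24))]),
        expected_alerts=[(1, 1)],
        expected_warnings=[],
    ))
    s.append(Scenario(
        "warning_nonrisk_drug",
        "Acetaminophen (not in the formulary) ordered during an open "
        "episode → no warning.",
        _patient("S19", [(_d(2), 100, C), (T, 160, H)],
                 orders=[MedicationOrder("S19", "acetaminophen", _h(24))]),
        expected_alerts=[(1, 1)],
        expected_warnings=[],
    ))
    s.append(Scenario(
        "warning_stage_attribution_after_progression",
        "Vancomycin ordered after the stage-2 progression alert carries "
        "stage 2, the highest stage alerted so far in the episode.",
        _patient("S20", [(_d(2), 100, C), (T, 160, H), (_h(12), 210, H)],
                 orders=[MedicationOrder("S20", "vancomycin", _h(18))]),
        expected_alerts=[(1, 1), (2, 1)],
        expected_warnings=[("vancomycin", 2)],
    ))
    s.append(Scenario(
        "multiclass_active_medication_listing",
        "At alert time the active-risk list holds the active diuretic and "
        "NSAID; the ACE inhibitor discontinued an hour earlier and the "
        "non-risk drug are excluded. Acknowledgment is idempotent and "
        "keeps the alert in history.",
        _patient(
            "S21",
            [(_d(2), 100, C), (T, 160, H)],
            orders=[
                MedicationOrder("S21", "furosemide", _d(1)),
                MedicationOrder("S21", "ibuprofen", _d(1)),
                MedicationOrder("S21", "ramipril", _d(1), discontinued_at=_h(-1)),
                MedicationOrder("S21", "acetaminophen", _d(1)),
            ],
        ),
        expected_alerts=[(1, 1)],
        expected_first_alert_meds=["furosemide", "ibuprofen"],
        check_acknowledgment=True,
    ))
    return s


@dataclass
class ScenarioResult:
    name: str
    passed: bool
    failures: list[str]


def run_scenario(
    scenario: Scenario,
    config: Optional[StagingConfig] = None,
    formulary: Optional[Formulary] = None,
) -> ScenarioResult:
    """Execute one scenario and compare the engine output with the
    expected alerts and warnings."""
    config = config or StagingConfig()
    formulary = formulary or Formulary.default()
    failures: list[str] = []

    result = detect(scenario.patient, config, formulary)
    got_alerts = [(a.stage, a.episode_index) for a in result.alerts]
    if got_alerts != scenario.expected_alerts:
        failures.append(
            f"alerts: expected {scenario.expected_alerts}, got {got_alerts}"
        )
    warnings = generate_warnings(scenario.patient, result.episodes, formulary, config)
    got_warnings = [(w.order.drug_name, w.aki_stage_at_order) for w in warnings]
    if got_warnings != scenario.expected_warnings:
        failures.append(
            f"warnings: expected {scenario.expected_warnings}, got {got_warnings}"
        )
    if scenario.expected_first_alert_meds is not None:
        got_meds = [m.drug_name for m in result.alerts[0].active_risk_medications] \
            if result.alerts else []
        if got_meds != scenario.expected_first_alert_meds:
            failures.append(
                f"first-alert meds: expected {scenario.expected_first_alert_meds}, "
                f"got {got_meds}"
            )
    if scenario.expected_baseline_method is not None and result.alerts:
        got = result.alerts[0].assessment.baseline.method.value
        if got != scenario.expected_baseline_method:
            failures.append(
                f"baseline method: expected {scenario.expected_baseline_method}, got {got}"
            )
    if scenario.check_acknowledgment and result.alerts:
        first = result.alerts[0]
        acked = acknowledge_alert(first, first.raised_at + timedelta(hours=2))
        again = acknowledge_alert(acked, first.raised_at + timedelta(hours=5))
        if acked.status is not AlertStatus.ACKNOWLEDGED or again != acked:
            failures.append("acknowledgment not idempotent")
    return ScenarioResult(scenario.name, not failures, failures)


def run_all_scenarios(
    config: Optional[StagingConfig] = None,
    formulary: Optional[Formulary] = None,
) -> list[ScenarioResult]:
    return [run_scenario(s, config, formulary) for s in fixture_scenarios()]
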