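"""Silent-mode batch evaluation over a cohort.

Runs the detection and medication-warning engines over every patient
with no display side effects and aggregates the frequency tables used
to audit alert volumes before go-live: alerts by stage, alerts with
active risk medications, medication classes listed on alerts, alerts by
unit type, and the same breakdowns for interruptive medication
warnings. Percentages are rounded half-away-from-zero to one decimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from .detection import AlertEvent, StagingConfig, detect
from .medsafety import Formulary, MedicationWarning, generate_warnings
from .records import Cohort, DrugClass, Patient, UnitType

#: Risk classes reported in the medication breakdowns, in table order.
REPORT_CLASSES = (
    DrugClass.DIURETIC,
    DrugClass.ANTIBIOTIC,
    DrugClass.ACEI_ARB,
    DrugClass.NSAID,
)


def percent(count: int, total: int) -> Optional[float]:
    """100·count/total rounded half-away-from-zero to one decimal;
    None when the partition total is zero."""
    if total == 0:
        return None
    q = (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass
class Cell:
    """One 'N (P)' table cell."""

    count: int
    pct: Optional[float]

    def __str__(self) -> str:
        return f"{self.count} ({'—' if self.pct is None else f'{self.pct:.1f}'})"


def _partition(counts: dict, total: int) -> dict:
    return {k: Cell(v, percent(v, total)) for k, v in counts.items()}


@dataclass
class CohortReport:
    total_alerts: int
    alerts_by_stage: dict[int, Cell]
    alerts_with_active_meds: Cell
    active_meds_by_class: dict[str, Cell]
    alerts_by_unit_type: dict[str, Cell]
    total_warnings: int
    warnings_by_stage: dict[int, Cell]
    warnings_by_med_class: dict[str, Cell]
    warnings_by_unit_type: dict[str, Cell]


def build_report(
    alerts: Sequence[AlertEvent],
    warnings: Sequence[MedicationWarning],
    cohort: Cohort,
) -> CohortReport:
    """Aggregate the raw alert and warning lists into frequency tables.

    Each alert contributes each distinct medication class at most once
    to the per-class breakdown; unit type is the type of the encounter
    during which the alert/warning was raised.
    """
    patients = {p.patient_id: p for p in cohort}

    def unit_type_of(patient_id: str, at) -> Optional[str]:
        enc = patients[patient_id].encounter_at(at)
        return enc.unit_type.value if enc else None

    n_alerts = len(alerts)
    stage_counts = {s: 0 for s in (1, 2, 3)}
    unit_counts = {u.value: 0 for u in UnitType}
    class_counts = {c.value: 0 for c in REPORT_CLASSES}
    with_meds = 0
    for a in alerts:
        stage_counts[a.stage] += 1
        u = unit_type_of(a.patient_id, a.raised_at)
        if u is not None:
            unit_counts[u] += 1
        if a.active_risk_medications:
            with_meds += 1
            for cls in sorted({m.drug_class for m in a.active_risk_medications if m.drug_class}):
                if cls.value in class_counts:
                    class_counts[cls.value] += 1

    n_warn = len(warnings)
    w_stage = {s: 0 for s in (1, 2, 3)}
    w_class = {c.value: 0 for c in REPORT_CLASSES}
    w_unit = {u.value: 0 for u in UnitType}
    for w in warnings:
        w_stage[w.aki_stage_at_order] += 1
        if w.order.drug_class and w.order.drug_class.value in w_class:
            w_class[w.order.drug_class.value] += 1
        u = unit_type_of(w.patient_id, w.raised_at)
        if u is not None:
            w_unit[u] += 1

    return CohortReport(
        total_alerts=n_alerts,
        alerts_by_stage=_partition(stage_counts, n_alerts),
        alerts_with_active_meds=Cell(with_meds, percent(with_meds, n_alerts)),
        active_meds_by_class=_partition(class_counts, n_alerts),
        alerts_by_unit_type=_partition(unit_counts, n_alerts),
        total_warnings=n_warn,
        warnings_by_stage=_partition(w_stage, n_warn),
        warnings_by_med_class=_partition(w_class, n_warn),
        warnings_by_unit_type=_partition(w_unit, n_warn),
    )


def run_silent(
    cohort: Cohort,
    config: Optional[StagingConfig] = None,
    formulary: Optional[Formulary] = None,
) -> tuple[list[AlertEvent], list[MedicationWarning], CohortReport]:
    """Run detection and the warning engine over every patient and
    aggregate the silent-phase report."""
    config = config or StagingConfig()
    formulary = formulary or Formulary.default()
    alerts: list[AlertEvent] = []
    warnings: list[MedicationWarning] = []
    for patient in cohort:
        result = detect(patient, config, formulary)
        alerts.extend(result.alerts)
        warnings.extend(
            generate_warnings(patient, result.episodes, formulary, config)
        )
    return alerts, warnings, build_report(alerts, warnings, cohort)


_CLASS_LABELS = {
    "diuretic": "Diuretics",
    "antibiotic": "Antibiotics",
    "acei_arb": "ACE-I/ARB",
    "nsaid": "NSAIDs",
}


def format_report(report: CohortReport) -> str:
    """Stable, diff-able text rendering with 'N (P)' cells."""
    lines = ["Alert frequency", "=" * 48]
    lines.append(f"Total AKI alerts{'':<18}{report.total_alerts} (100.0)"
                 if report.total_alerts else f"Total AKI alerts{'':<18}0 (—)")

    def row(label: str, cell: Cell) -> str:
        return f"  {label:<32}{cell}"

    for s in (1, 2, 3):
        lines.append(row(f"Stage {s} AKI alerts", report.alerts_by_stage[s]))
    lines.append(row("With active risk medications", report.alerts_with_active_meds))
    for k in ("diuretic", "antibiotic", "acei_arb", "nsaid"):
        lines.append(row(_CLASS_LABELS[k], report.active_meds_by_class[k]))
    for u in ("medical", "surgical"):
        lines.append(row(f"{u.capitalize()} unit", report.alerts_by_unit_type[u]))
    lines.append("")
    lines.append("Adverse medication warning frequency")
    lines.append("=" * 48)
    lines.append(
        f"Total warnings{'':<20}{report.total_warnings} (100.0)"
        if report.total_warnings else f"Total warnings{'':<20}0 (—)"
    )
    for s in (1, 2, 3):
        lines.append(row(f"Stage {s} at warning", report.warnings_by_stage[s]))
    for k in ("diuretic", "antibiotic", "acei_arb", "nsaid"):
        lines.append(row(_CLASS_LABELS[k], report.warnings_by_med_class[k]))
    for u in ("medical", "surgical"):
        lines.append(row(f"{u.capitalize()} unit", report.warnings_by_unit_type[u]))
    return "\n".join(lines) + "\n"


def report_to_dict(report: CohortReport) -> dict:
    def part(d: dict) -> dict:
        return {str(k): {"count": c.count, "percent": c.pct} for k, c in d.items()}

    return {
        "total_alerts": report.total_alerts,
        "alerts_by_stage": part(report.alerts_by_stage),
        "alerts_with_active_meds": {
            "count": report.alerts_with_active_meds.count,
            "percent": report.alerts_with_active_meds.pct,
        },
        "active_meds_by_class": part(report.active_meds_by_class),
        "alerts_by_unit_type": part(report.alerts_by_unit_type),
        "total_warnings": report.total_warnings,
        "warnings_by_stage": part(report.warnings_by_stage),
        "warnings_by_med_class": part(report.warnings_by_med_class),
        "warnings_by_unit_type": part(report.warnings_by_unit_type),
    }


def report_to_json(report: CohortReport, indent: int = 2) -> str:
    return json.dumps(report_to_dict(report), indent=indent)
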