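"""Clinical-summary aggregation for one patient.

Assembles, as of a chosen timestamp, everything a provider assessing
AKI wants in one view: the permanent alert history, creatinine / urea /
electrolyte trends, the two medication panels (may worsen AKI; renally
cleared), per-interval urine output and fluid balance, IV therapies,
vital signs, infection markers (white cell count, urinalysis, urine
protein, free-text cultures) and the visit history. The summary is a
pure function of the events at or before ``as_of``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence

from .detection import AlertEvent
from .medsafety import Formulary
from .records import (
    Analyte,
    Encounter,
    FluidKind,
    FluidRecord,
    LabResult,
    MedicationOrder,
    Patient,
    VitalSign,
    format_timestamp,
)

#: Analytes shown in the electrolyte panel by default.
DEFAULT_ELECTROLYTES = (Analyte.SODIUM, Analyte.POTASSIUM, Analyte.BICARBONATE)

TrendPoint = tuple[datetime, float]
Interval = tuple[datetime, datetime]


@dataclass
class DashboardSummary:
    patient_id: str
    as_of: datetime
    alert_history: list[AlertEvent]
    creatinine_trend: list[TrendPoint]
    urea_trend: list[TrendPoint]
    electrolyte_trends: dict[str, list[TrendPoint]]
    meds_may_worsen_aki: list[MedicationOrder]
    meds_renally_cleared: list[MedicationOrder]
    urine_output_by_interval: list[tuple[Interval, float]]
    fluid_balance_by_interval: list[tuple[Interval, float]]
    iv_therapies: list[FluidRecord]
    vitals: list[VitalSign]
    infection_markers: dict[str, list]
    visit_history: list[Encounter]


def fluid_balance(fluids: Sequence[FluidRecord], interval: Interval) -> float:
    """Net fluid balance (mL) over a half-open interval [start, end):
    total intake minus total output; 0 when no records fall inside."""
    start, end = interval
    net = 0.0
    for f in fluids:
        if start <= f.recorded_at < end:
            net += f.volume if f.kind.is_intake else -f.volume
    return net


def urine_output_rate(
    fluids: Sequence[FluidRecord],
    interval: Interval,
    weight_kg: Optional[float] = None,
) -> tuple[float, Optional[float]]:
    """Total urine output (mL) in [start, end) and, when a weight is
    given, the rate in mL/kg/h."""
    start, end = interval
    hours = (end - start).total_seconds() / 3600.0
    if hours <= 0:
        raise ValueError("interval duration must be > 0")
    total = sum(
        f.volume
        for f in fluids
        if f.kind is FluidKind.OUTPUT_URINE and start <= f.recorded_at < end
    )
    if weight_kg is None:
        return total, None
    if weight_kg <= 0:
        raise ValueError("weight_kg must be > 0")
    return total, total / weight_kg / hours


def _trend(labs: Sequence[LabResult], analyte: Analyte, as_of: datetime) -> list[TrendPoint]:
    return [
        (r.collected_at, r.value)
        for r in labs
        if r.analyte is analyte and r.collected_at <= as_of and r.value is not None
    ]


def _intervals(anchor: datetime, as_of: datetime, width: timedelta) -> list[Interval]:
    # full-width bins; the last one may extend past as_of (records are
    # already truncated at as_of upstream)
    out = []
    start = anchor
    while start < as_of:
        out.append((start, start + width))
        start = start + width
    return out


def build_dashboard(
    patient: Patient,
    alerts: Sequence[AlertEvent],
    formulary: Optional[Formulary] = None,
    as_of: Optional[datetime] = None,
    interval_width: timedelta = timedelta(hours=8),
    electrolytes: Sequence[Analyte] = DEFAULT_ELECTROLYTES,
) -> DashboardSummary:
    """Assemble the summary view for one patient as of ``as_of``.

    Events after ``as_of`` are excluded everywhere; acknowledged alerts
    stay in the history (alerts are permanently retained). Fluid
    summaries use half-open intervals of ``interval_width`` (default 8 h
    — nursing-shift granularity) anchored at the admission of the
    encounter covering ``as_of``, falling back to the first fluid
    record.
    """
    formulary = formulary or Formulary.default()
    if as_of is None:
        times = [r.collected_at for r in patient.labs]
        times += [o.ordered_at for o in patient.medication_orders]
        times += [f.recorded_at for f in patient.fluids]
        times += [v.recorded_at for v in patient.vitals]
        times += [e.admit_time for e in patient.encounters]
        as_of = max(times) if times else datetime.now().astimezone()

    worsen: list[MedicationOrder] = []
    renal: list[MedicationOrder] = []
    for o in patient.medication_orders:
        if o.ordered_at > as_of:
            continue
        profile = formulary.lookup(o.drug_name)
        o.drug_class = profile.risk_class
        # a drug with both flags appears in both panels
        if profile.may_cause_aki:
            worsen.append(o)
        if profile.renally_cleared:
            renal.append(o)

    enc = patient.encounter_at(as_of)
    fluids = [f for f in patient.fluids if f.recorded_at <= as_of]
    if enc is not None:
        anchor = enc.admit_time
    elif fluids:
        anchor = fluids[0].recorded_at
    else:
        anchor = as_of
    intervals = _intervals(anchor, as_of, interval_width)

    urine = [
        (iv, urine_output_rate(fluids, iv)[0])
        for iv in intervals
    ]
    balance = [(iv, fluid_balance(fluids, iv)) for iv in intervals]

    return DashboardSummary(
        patient_id=patient.patient_id,
        as_of=as_of,
        alert_history=[a for a in alerts if a.raised_at <= as_of],
        creatinine_trend=_trend(patient.labs, Analyte.CREATININE, as_of),
        urea_trend=_trend(patient.labs, Analyte.UREA, as_of),
        electrolyte_trends={
            a.value: _trend(patient.labs, a, as_of) for a in electrolytes
        },
        meds_may_worsen_aki=worsen,
        meds_renally_cleared=renal,
        urine_output_by_interval=urine,
        fluid_balance_by_interval=balance,
        iv_therapies=[f for f in fluids if f.kind is FluidKind.INTAKE_IV],
        vitals=[v for v in patient.vitals if v.recorded_at <= as_of],
        infection_markers={
            "wbc_trend": _trend(patient.labs, Analyte.WBC, as_of),
            "urinalysis": [
                r for r in patient.labs
                if r.analyte is Analyte.URINALYSIS and r.collected_at <= as_of
            ],
            "urine_protein": [
                r for r in patient.labs
                if r.analyte is Analyte.URINE_PROTEIN and r.collected_at <= as_of
            ],
            "cultures": [
                r for r in patient.labs
                if r.analyte is Analyte.OTHER and r.text and r.collected_at <= as_of
            ],
        },
        visit_history=[e for e in patient.encounters if e.admit_time <= as_of],
    )


def _iv(interval: Interval) -> list[str]:
    return [format_timestamp(interval[0]), format_timestamp(interval[1])]


def dashboard_to_dict(s: DashboardSummary) -> dict:
    """Canonical JSON-serializable form of a dashboard summary."""
    return {
        "patient_id": s.patient_id,
        "as_of": format_timestamp(s.as_of),
        "alert_history": [
            {
                "alert_id": a.alert_id,
                "stage": a.stage,
                "raised_at": format_timestamp(a.raised_at),
                "status": a.status.value,
                "episode_index": a.episode_index,
                "active_risk_medications": [m.drug_name for m in a.active_risk_medications],
            }
            for a in s.alert_history
        ],
        "creatinine_trend": [[format_timestamp(t), v] for t, v in s.creatinine_trend],
        "urea_trend": [[format_timestamp(t), v] for t, v in s.urea_trend],
        "electrolyte_trends": {
            k: [[format_timestamp(t), v] for t, v in pts]
            for k, pts in s.electrolyte_trends.items()
        },
        "meds_may_worsen_aki": [
            {"drug_name": o.drug_name, "drug_class": o.drug_class.value if o.drug_class else None,
             "ordered_at": format_timestamp(o.ordered_at)}
            for o in s.meds_may_worsen_aki
        ],
        "meds_renally_cleared": [
            {"drug_name": o.drug_name, "ordered_at": format_timestamp(o.ordered_at)}
            for o in s.meds_renally_cleared
        ],
        "urine_output_by_interval": [
            {"interval": _iv(iv), "total_ml": total} for iv, total in s.urine_output_by_interval
        ],
        "fluid_balance_by_interval": [
            {"interval": _iv(iv), "net_ml": net} for iv, net in s.fluid_balance_by_interval
        ],
        "iv_therapies": [
            {"recorded_at": format_timestamp(f.recorded_at), "volume_ml": f.volume}
            for f in s.iv_therapies
        ],
        "vitals": [
            {"kind": v.kind.value, "value": v.value, "recorded_at": format_timestamp(v.recorded_at)}
            for v in s.vitals
        ],
        "infection_markers": {
            "wbc_trend": [[format_timestamp(t), v] for t, v in s.infection_markers["wbc_trend"]],
            "urinalysis": [
                {"collected_at": format_timestamp(r.collected_at), "value": r.value, "text": r.text}
                for r in s.infection_markers["urinalysis"]
            ],
            "urine_protein": [
                {"collected_at": format_timestamp(r.collected_at), "value": r.value, "text": r.text}
                for r in s.infection_markers["urine_protein"]
            ],
            "cultures": [
                {"collected_at": format_timestamp(r.collected_at), "text": r.text}
                for r in s.infection_markers["cultures"]
            ],
        },
        "visit_history": [
            {
                "encounter_id": e.encounter_id,
                "admit_time": format_timestamp(e.admit_time),
                "discharge_time": format_timestamp(e.discharge_time) if e.discharge_time else None,
                "unit_type": e.unit_type.value,
                "unit_name": e.unit_name,
            }
            for e in s.visit_history
        ],
    }


def dashboard_to_json(s: DashboardSummary, indent: int = 2) -> str:
    return json.dumps(dashboard_to_dict(s), indent=indent)


def dashboard_to_html(s: DashboardSummary) -> str:
    """Render a single self-contained HTML page (static, no scripts)."""
    d = dashboard_to_dict(s)

    def table(rows: list[list], headers: list[str]) -> str:
        head = "".join(f"<th>{h}</th>" for h in headers)
        body = "".join(
            "<tr>" + "".join(f"<td>{c if c is not None else ''}</td>" for c in row) + "</tr>"
            for row in rows
        )
        return f"<table><tr>{head}</tr>{body}</table>"

    sections = [
        ("AKI alert history", table(
            [[a["raised_at"], a["stage"], a["status"], a["episode_index"],
              ", ".join(a["active_risk_medications"])] for a in d["alert_history"]],
            ["Raised", "Stage", "Status", "Episode", "Risk medications"])),
        ("Creatinine (µmol/L)", table(d["creatinine_trend"], ["Time", "Value"])),
        ("Urea", table(d["urea_trend"], ["Time", "Value"])),
        ("Medications that may worsen AKI", table(
            [[m["drug_name"], m["drug_class"], m["ordered_at"]] for m in d["meds_may_worsen_aki"]],
            ["Drug", "Class", "Ordered"])),
        ("Renally cleared medications", table(
            [[m["drug_name"], m["ordered_at"]] for m in d["meds_renally_cleared"]],
            ["Drug", "Ordered"])),
        ("Urine output by interval", table(
            [[*r["interval"], r["total_ml"]] for r in d["urine_output_by_interval"]],
            ["From", "To", "mL"])),
        ("Fluid balance by interval", table(
            [[*r["interval"], r["net_ml"]] for r in d["fluid_balance_by_interval"]],
            ["From", "To", "Net mL"])),
        ("Vital signs", table(
            [[v["recorded_at"], v["kind"], v["value"]] for v in d["vitals"]],
            ["Time", "Kind", "Value"])),
        ("Visit history", table(
            [[e["admit_time"], e["discharge_time"], e["unit_type"], e["unit_name"]]
             for e in d["visit_history"]],
            ["Admitted", "Discharged", "Unit type", "Unit"])),
    ]
    body = "".join(f"<h2>{title}</h2>{html}" for title, html in sections)
    return (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>AKI summary — {d['patient_id']}</title>"
        "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:2px 8px;font-size:0.9em}</style></head>"
        f"<body><h1>AKI clinical summary — patient {d['patient_id']}</h1>"
        f"<p>As of {d['as_of']}</p>{body}</body></html>"
    )
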