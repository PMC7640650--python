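"""Readers and writers for on-disk patient event streams.

Two equivalent formats are supported: a flat CSV (comma-separated,
UTF-8, header row required) and JSON-lines. Every row/object carries a
``record_kind`` discriminator naming one of the five event types
(encounter, lab, med_order, fluid, vital) plus kind-specific payload
fields. JSON Schema files describing both layouts ship under
``aki_cds/data/schemas/``.

Rows that violate an invariant (malformed timestamp, missing
patient_id, non-positive quantitative value, unknown record kind) are
reported with their 1-based row index; an empty file yields an empty
cohort.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

from .records import (
    MG_DL_TO_UMOL_L,
    Analyte,
    Cohort,
    DrugClass,
    Encounter,
    FluidKind,
    FluidRecord,
    LabResult,
    MedicationOrder,
    Patient,
    Setting,
    UnitType,
    VitalKind,
    VitalSign,
    format_timestamp,
    parse_timestamp,
)

CSV_COLUMNS = [
    "record_kind",
    "patient_id",
    "encounter_id",
    "timestamp",
    "analyte",
    "value",
    "text",
    "setting",
    "drug_name",
    "discontinued_at",
    "fluid_kind",
    "volume",
    "vital_kind",
    "unit_type",
    "unit_name",
    "discharge_time",
]

RECORD_KINDS = ("encounter", "lab", "med_order", "fluid", "vital")


@dataclass
class RowError:
    row: int  # 1-based data-row index (header excluded for CSV)
    message: str

    def __str__(self) -> str:
        return f"row {self.row}: {self.message}"


class EventStreamError(ValueError):
    """Raised when an event-stream file contains invalid rows."""

    def __init__(self, errors: list[RowError]):
        self.errors = errors
        super().__init__(
            "invalid event stream: " + "; ".join(str(e) for e in errors[:10])
            + ("" if len(errors) <= 10 else f" (+{len(errors) - 10} more)")
        )


def _parse_row(rec: dict[str, Any], creatinine_unit: str) -> tuple[str, str, Any]:
    """Turn one raw record into (patient_id, record_kind, event object).

    Raises ValueError with a human-readable message on any invariant
    violation; the caller attaches the row index.
    """
    kind = (rec.get("record_kind") or "").strip()
    if kind not in RECORD_KINDS:
        raise ValueError(f"unknown record_kind {kind!r}")
    patient_id = (rec.get("patient_id") or "").strip()
    if not patient_id:
        raise ValueError("missing patient_id")
    ts_raw = (rec.get("timestamp") or "").strip()
    if not ts_raw:
        raise ValueError("missing timestamp")
    try:
        ts = parse_timestamp(ts_raw)
    except ValueError as exc:
        raise ValueError(f"malformed timestamp {ts_raw!r}: {exc}") from None

    def opt_ts(key: str):
        raw = rec.get(key)
        if raw is None or str(raw).strip() == "":
            return None
        try:
            return parse_timestamp(str(raw).strip())
        except ValueError as exc:
            raise ValueError(f"malformed {key} {raw!r}: {exc}") from None

    def opt_float(key: str) -> Optional[float]:
        raw = rec.get(key)
        if raw is None or str(raw).strip() == "":
            return None
        try:
            return float(raw)
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric {key} {raw!r}") from None

    if kind == "encounter":
        event: Any = Encounter(
            encounter_id=(rec.get("encounter_id") or "").strip() or f"enc-{patient_id}",
            admit_time=ts,
            discharge_time=opt_ts("discharge_time"),
            unit_type=UnitType((rec.get("unit_type") or "medical").strip()),
            unit_name=(rec.get("unit_name") or "").strip(),
        )
    elif kind == "lab":
        analyte = Analyte((rec.get("analyte") or "").strip())
        value = opt_float("value")
        if analyte is Analyte.CREATININE and value is not None and creatinine_unit == "mg_dl":
            value *= MG_DL_TO_UMOL_L
        text = rec.get("text")
        event = LabResult(
            patient_id=patient_id,
            analyte=analyte,
            collected_at=ts,
            value=value,
            text=str(text) if text not in (None, "") else None,
            setting=Setting((rec.get("setting") or "hospital").strip()),
        )
    elif kind == "med_order":
        event = MedicationOrder(
            patient_id=patient_id,
            drug_name=(rec.get("drug_name") or "").strip(),
            ordered_at=ts,
            discontinued_at=opt_ts("discontinued_at"),
        )
    elif kind == "fluid":
        volume = opt_float("volume")
        if volume is None:
            raise ValueError("fluid record requires a volume")
        event = FluidRecord(
            patient_id=patient_id,
            kind=FluidKind((rec.get("fluid_kind") or "").strip()),
            volume=volume,
            recorded_at=ts,
        )
    else:  # vital
        value = opt_float("value")
        if value is None:
            raise ValueError("vital record requires a value")
        event = VitalSign(
            patient_id=patient_id,
            kind=VitalKind((rec.get("vital_kind") or "").strip()),
            value=value,
            recorded_at=ts,
        )
    return patient_id, kind, event


def _assemble(raw_records: list[dict[str, Any]], creatinine_unit: str) -> Cohort:
    errors: list[RowError] = []
    patients: dict[str, Patient] = {}
    for i, rec in enumerate(raw_records, start=1):
        try:
            patient_id, kind, event = _parse_row(rec, creatinine_unit)
        except ValueError as exc:
            errors.append(RowError(i, str(exc)))
            continue
        patient = patients.setdefault(patient_id, Patient(patient_id=patient_id))
        if kind == "encounter":
            patient.encounters.append(event)
        elif kind == "lab":
            patient.labs.append(event)
        elif kind == "med_order":
            patient.medication_orders.append(event)
        elif kind == "fluid":
            patient.fluids.append(event)
        else:
            patient.vitals.append(event)
    if errors:
        raise EventStreamError(errors)
    for patient in patients.values():
        patient.sort_events()
    return Cohort(patients=list(patients.values()))


def read_event_stream(
    path: str | Path, format: str = "csv", creatinine_unit: str = "umol_l"
) -> Cohort:
    """Read a cohort from a CSV or JSON-lines event-stream file.

    Parameters
    ----------
    path
        Existing file. An empty file (or header-only CSV) yields an
        empty cohort.
    format
        ``"csv"`` or ``"jsonl"``.
    creatinine_unit
        ``"umol_l"`` (default) or ``"mg_dl"``; mg/dL creatinine values
        are converted to µmol/L (×88.4) at read time.
    """
    path = Path(path)
    if creatinine_unit not in ("umol_l", "mg_dl"):
        raise ValueError(f"unknown creatinine_unit {creatinine_unit!r}")
    if format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            raw = list(csv.DictReader(fh))
    elif format == "jsonl":
        raw = []
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    raw.append(json.loads(line))
    else:
        raise ValueError(f"unknown format {format!r}")
    return _assemble(raw, creatinine_unit)


def _event_rows(cohort: Cohort) -> list[dict[str, Any]]:
    rows: list[dict[str, Any]] = []

    def row(kind: str, patient_id: str, ts, **payload: Any) -> None:
        rows.append({"record_kind": kind, "patient_id": patient_id,
                     "timestamp": format_timestamp(ts), **payload})

    for p in cohort:
        for e in p.encounters:
            row(
                "encounter", p.patient_id, e.admit_time,
                encounter_id=e.encounter_id,
                discharge_time=format_timestamp(e.discharge_time) if e.discharge_time else None,
                unit_type=e.unit_type.value, unit_name=e.unit_name,
            )
        for r in p.labs:
            row(
                "lab", p.patient_id, r.collected_at,
                analyte=r.analyte.value, value=r.value, text=r.text,
                setting=r.setting.value,
            )
        for o in p.medication_orders:
            row(
                "med_order", p.patient_id, o.ordered_at,
                drug_name=o.drug_name,
                discontinued_at=format_timestamp(o.discontinued_at) if o.discontinued_at else None,
            )
        for f in p.fluids:
            row("fluid", p.patient_id, f.recorded_at,
                fluid_kind=f.kind.value, volume=f.volume)
        for v in p.vitals:
            row("vital", p.patient_id, v.recorded_at,
                vital_kind=v.kind.value, value=v.value)
    return rows


def write_event_stream(cohort: Cohort, path: str | Path, format: str = "csv") -> None:
    """Write a cohort so that reading it back reproduces every event.

    A zero-patient cohort produces a header-only CSV or an empty JSONL
    file.
    """
    path = Path(path)
    rows = _event_rows(cohort)
    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
            writer.writeheader()
            for r in rows:
                writer.writerow({k: ("" if r.get(k) is None else r.get(k, "")) for k in CSV_COLUMNS})
    elif format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in rows:
                fh.write(json.dumps({k: v for k, v in r.items() if v is not None}) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
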