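"""Domain types for longitudinal hospital patient event streams.

Every clinical event carries a timezone-aware UTC timestamp. Serum
creatinine is expressed in µmol/L throughout (the Canadian laboratory
convention); readers can convert mg/dL inputs at load time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Optional

MG_DL_TO_UMOL_L = 88.4


class Analyte(str, enum.Enum):
    CREATININE = "creatinine"
    UREA = "urea"
    SODIUM = "sodium"
    POTASSIUM = "potassium"
    BICARBONATE = "bicarbonate"
    WBC = "wbc"
    URINALYSIS = "urinalysis"
    URINE_PROTEIN = "urine_protein"
    OTHER = "other"


#: Analytes whose ``value`` must be a positive number.
QUANTITATIVE_ANALYTES = frozenset(
    {
        Analyte.CREATININE,
        Analyte.UREA,
        Analyte.SODIUM,
        Analyte.POTASSIUM,
        Analyte.BICARBONATE,
        Analyte.WBC,
    }
)


class Setting(str, enum.Enum):
    """Where a laboratory specimen was drawn.

    Only hospital creatinine results act as index values for AKI
    staging; community (pre-admission) results remain eligible as
    baseline material.
    """

    HOSPITAL = "hospital"
    COMMUNITY = "community"


class DrugClass(str, enum.Enum):
    DIURETIC = "diuretic"
    ANTIBIOTIC = "antibiotic"
    ACEI_ARB = "acei_arb"
    NSAID = "nsaid"
    RENALLY_CLEARED = "renally_cleared"
    OTHER = "other"


class FluidKind(str, enum.Enum):
    INTAKE_IV = "intake_iv"
    INTAKE_ORAL = "intake_oral"
    OUTPUT_URINE = "output_urine"
    OUTPUT_OTHER = "output_other"

    @property
    def is_intake(self) -> bool:
        return self in (FluidKind.INTAKE_IV, FluidKind.INTAKE_ORAL)


class VitalKind(str, enum.Enum):
    HEART_RATE = "heart_rate"
    SYSTOLIC_BP = "systolic_bp"
    DIASTOLIC_BP = "diastolic_bp"


class UnitType(str, enum.Enum):
    MEDICAL = "medical"
    SURGICAL = "surgical"


def parse_timestamp(raw: str) -> datetime:
    """Parse an ISO-8601 timestamp; naive values are taken as UTC.

    All comparisons inside the package happen on timezone-aware UTC
    datetimes, so mixed-offset inputs behave consistently.
    """
    dt = datetime.fromisoformat(raw.replace("Z", "+00:00"))
    if dt.tzinfo is None:
        return dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


def format_timestamp(dt: datetime) -> str:
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc).isoformat().replace("+00:00", "Z")


def utc(year: int, month: int, day: int, hour: int = 0, minute: int = 0) -> datetime:
    """Convenience constructor for UTC timestamps."""
    return datetime(year, month, day, hour, minute, tzinfo=timezone.utc)


@dataclass
class Encounter:
    """One hospital stay: an admission, optionally a discharge, and the
    unit (medical vs surgical) where the patient is located."""

    encounter_id: str
    admit_time: datetime
    discharge_time: Optional[datetime] = None
    unit_type: UnitType = UnitType.MEDICAL
    unit_name: str = ""

    def __post_init__(self) -> None:
        if self.discharge_time is not None and self.discharge_time < self.admit_time:
            raise ValueError(
                f"encounter {self.encounter_id}: discharge_time precedes admit_time"
            )

    def contains(self, at: datetime) -> bool:
        if at < self.admit_time:
            return False
        return self.discharge_time is None or at <= self.discharge_time


@dataclass
class LabResult:
    """A timestamped analyte measurement.

    ``value`` is required and positive for quantitative analytes;
    non-quantitative results (urinalysis, urine protein, microbiology
    passed through as ``other``) may use ``text`` instead.
    """

    patient_id: str
    analyte: Analyte
    collected_at: datetime
    value: Optional[float] = None
    text: Optional[str] = None
    setting: Setting = Setting.HOSPITAL

    def __post_init__(self) -> None:
        if self.analyte in QUANTITATIVE_ANALYTES:
            if self.value is None or self.value <= 0:
                raise ValueError(
                    f"{self.analyte.value} result requires a positive value, "
                    f"got {self.value!r}"
                )


@dataclass
class MedicationOrder:
    """A medication order with optional discontinuation.

    ``drug_class`` is derived from the formulary by normalized drug
    name; it is filled lazily by the medication-safety module and is
    not trusted from input files.
    """

    patient_id: str
    drug_name: str
    ordered_at: datetime
    discontinued_at: Optional[datetime] = None
    drug_class: Optional[DrugClass] = None

    def __post_init__(self) -> None:
        if not self.drug_name or not self.drug_name.strip():
            raise ValueError("medication order requires a drug_name")
        if self.discontinued_at is not None and self.discontinued_at < self.ordered_at:
            raise ValueError(
                f"order of {self.drug_name!r}: discontinued_at precedes ordered_at"
            )

    def active_at(self, at: datetime) -> bool:
        """Order is active on [ordered_at, discontinued_at)."""
        if at < self.ordered_at:
            return False
        return self.discontinued_at is None or at < self.discontinued_at


@dataclass
class FluidRecord:
    patient_id: str
    kind: FluidKind
    volume: float  # mL
    recorded_at: datetime

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError(f"fluid volume must be >= 0, got {self.volume}")


@dataclass
class VitalSign:
    patient_id: str
    kind: VitalKind
    value: float
    recorded_at: datetime

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"vital sign value must be > 0, got {self.value}")


@dataclass
class Patient:
    """All events for one patient, each list sorted ascending by time
    (ties broken by insertion order)."""

    patient_id: str
    encounters: list[Encounter] = field(default_factory=list)
    labs: list[LabResult] = field(default_factory=list)
    medication_orders: list[MedicationOrder] = field(default_factory=list)
    fluids: list[FluidRecord] = field(default_factory=list)
    vitals: list[VitalSign] = field(default_factory=list)

    def sort_events(self) -> None:
        # sorted() is stable, so same-timestamp events keep input order
        self.encounters.sort(key=lambda e: e.admit_time)
        self.labs.sort(key=lambda r: r.collected_at)
        self.medication_orders.sort(key=lambda o: o.ordered_at)
        self.fluids.sort(key=lambda f: f.recorded_at)
        self.vitals.sort(key=lambda v: v.recorded_at)

    def encounter_at(self, at: datetime) -> Optional[Encounter]:
        """The encounter whose stay covers ``at``, if any."""
        for enc in self.encounters:
            if enc.contains(at):
                return enc
        return None

    def creatinine(self) -> list[LabResult]:
        return [r for r in self.labs if r.analyte is Analyte.CREATININE]


@dataclass
class Cohort:
    """An ordered collection of patients with unique identifiers."""

    patients: list[Patient] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_id(s) in cohort: {dupes}")

    def __iter__(self) -> Iterable[Patient]:
        return iter(self.patients)

    def __len__(self) -> int:
        return len(self.patients)

    def get(self, patient_id: str) -> Patient:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)
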