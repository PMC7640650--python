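"""Seeded synthetic-cohort generator.

Emulates the population a silent-alerting audit would run over: general
medical/surgical inpatients with routine creatinine draws, a minority
of whom develop an in-hospital AKI episode. Creatinine trajectories are
piecewise — flat around a personal lognormal baseline, a step up into
the planted stage's KDIGO ratio band (placed at least 5% inside the
band edges so measurement noise cannot move the planted stage), an
optional escalation step for progression, then a step back to baseline
on recovery. Measurement noise is multiplicative lognormal with a
configurable coefficient of variation.

The generator also plants risk-medication orders, fluid charting and
vital signs, and returns the ground truth (episode onsets, peak stages,
recovery times, in-window order flags) alongside the event stream, so
detection can be scored against what was planted.

Identical seeds produce byte-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .records import (
    Cohort,
    Encounter,
    FluidKind,
    FluidRecord,
    LabResult,
    Analyte,
    MedicationOrder,
    Patient,
    Setting,
    UnitType,
    VitalKind,
    VitalSign,
    utc,
)

#: Start of the simulated observation window.
EPOCH = utc(2025, 1, 1)

#: Ratio bands per planted stage, already 5% inside the KDIGO band
#: edges (1.5/2.0/3.0) so noise cannot cross a stage boundary.
STAGE_BANDS = {1: (1.575, 1.90), 2: (2.10, 2.85), 3: (3.15, 3.60)}

#: KDIGO absolute stage-3 creatinine threshold (µmol/L). A planted
#: stage-1/2 ratio on a high-baseline patient can cross it, in which
#: case the truly planted stage is 3 and the truth records that.
ABS_STAGE3_UMOL_L = 353.6


def _planted_stage(band_stage: int, peak_value: float) -> int:
    return 3 if round(peak_value, 1) >= ABS_STAGE3_UMOL_L else band_stage

_CLASS_AGENTS = {
    "diuretic": ["furosemide", "hydrochlorothiazide", "spironolactone"],
    "antibiotic": ["vancomycin", "gentamicin", "tobramycin"],
    "acei_arb": ["ramipril", "candesartan", "lisinopril"],
    "nsaid": ["ibuprofen", "naproxen", "ketorolac"],
}
_RENAL_AGENTS = ["digoxin", "metformin", "gabapentin"]
_NEUTRAL_AGENTS = ["acetaminophen", "pantoprazole", "ondansetron"]


class SimulationConfig(BaseModel):
    """Knobs of the synthetic population; defaults emulate a month of
    silent observation on general medical and surgical units."""

    n_patients: int = Field(default=400, gt=0)
    observation_days: int = Field(default=30, gt=0)
    stay_days: tuple[float, float] = (4.0, 10.0)
    lab_sampling_interval_hours: tuple[float, float] = (12.0, 24.0)
    baseline_lognormal_mu: float = math.log(80.0)  # ln µmol/L
    baseline_lognormal_sigma: float = 0.25
    aki_incidence: float = Field(default=0.15, ge=0, le=1)
    stage_mix: tuple[float, float, float] = (0.667, 0.173, 0.160)
    progression_probability: float = Field(default=0.15, ge=0, le=1)
    recovery_probability_per_day: float = Field(default=0.5, gt=0, le=1)
    risk_med_exposure: dict[str, float] = Field(
        default_factory=lambda: {
            "diuretic": 0.25,
            "antibiotic": 0.20,
            "acei_arb": 0.20,
            "nsaid": 0.15,
        }
    )
    measurement_noise_cv: float = Field(default=0.02, ge=0)
    unit_mix_surgical: float = Field(default=0.3, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        bad = []
        if not self.stay_days[0] <= self.stay_days[1] or self.stay_days[0] <= 0:
            bad.append("stay_days")
        lo, hi = self.lab_sampling_interval_hours
        if not 0 < lo <= hi:
            bad.append("lab_sampling_interval_hours")
        if abs(sum(self.stage_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.stage_mix):
            bad.append("stage_mix")
        if any(not 0 <= p <= 1 for p in self.risk_med_exposure.values()):
            bad.append("risk_med_exposure")
        if bad:
            raise ValueError(f"invalid simulation config field(s): {', '.join(bad)}")
        return self


@dataclass
class PlantedEpisode:
    patient_id: str
    onset_at: "datetime"  # first elevated sample
    peak_stage: int
    recovery_at: "datetime"  # first back-to-baseline sample


@dataclass
class PlantedOrder:
    patient_id: str
    drug_name: str
    risk_class: Optional[str]
    in_window: bool  # within 48 h of a planted onset


@dataclass
class PlantedTruth:
    episodes: list[PlantedEpisode] = field(default_factory=list)
    orders: list[PlantedOrder] = field(default_factory=list)


def _minutes(rng: np.random.Generator, lo_h: float, hi_h: float) -> timedelta:
    return timedelta(minutes=int(rng.uniform(lo_h * 60, hi_h * 60)))


def generate_cohort(config: SimulationConfig) -> tuple[Cohort, PlantedTruth]:
    """Generate a cohort event stream plus its planted ground truth."""
    rng = np.random.default_rng(config.seed)
    truth = PlantedTruth()
    patients: list[Patient] = []

    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        patient = Patient(patient_id=pid)

        baseline = float(
            rng.lognormal(config.baseline_lognormal_mu, config.baseline_lognormal_sigma)
        )
        cv = config.measurement_noise_cv

        def noisy(value: float) -> float:
            if cv <= 0:
                return round(value, 1)
            return round(value * float(rng.lognormal(0.0, cv)), 1)

        admit = EPOCH + _minutes(rng, 0, config.observation_days * 24)
        stay_h = float(rng.uniform(config.stay_days[0] * 24, config.stay_days[1] * 24))
        surgical = bool(rng.random() < config.unit_mix_surgical)
        unit_type = UnitType.SURGICAL if surgical else UnitType.MEDICAL
        unit_name = f"{'Surg' if surgical else 'Med'}-{int(rng.integers(1, 8))}"

        # community creatinine history: year-median baseline material
        for _ in range(3):
            t = admit - timedelta(days=float(rng.uniform(30, 300)))
            patient.labs.append(
                LabResult(pid, Analyte.CREATININE, t, noisy(baseline),
                          setting=Setting.COMMUNITY)
            )

        interval_h = float(
            rng.uniform(*config.lab_sampling_interval_hours)
        )
        n_labs = max(3, int(stay_h / interval_h))
        lab_times = [
            admit + timedelta(hours=2) + timedelta(minutes=int(k * interval_h * 60))
            for k in range(n_labs)
        ]

        has_aki = bool(rng.random() < config.aki_incidence)
        plan: list[float] = [1.0] * n_labs  # planned ratio multiplier per lab
        if has_aki:
            stage = int(rng.choice([1, 2, 3], p=list(config.stage_mix)))
            onset_idx = int(rng.integers(2, 4))  # after 2-3 normal draws
            # elevated duration from the recovery hazard, capped so the
            # pre-onset baseline stays inside the 7-day window
            dwell_days = min(3, 1 + int(rng.geometric(config.recovery_probability_per_day)) - 1)
            n_elev = max(1, int(round(dwell_days * 24 / interval_h)))
            peak_stage = stage
            seg2 = 0
            if stage < 3 and rng.random() < config.progression_probability:
                peak_stage = stage + 1
                seg2 = max(1, int(round(24 / interval_h)))
                n_elev = min(n_elev, max(1, int(round(48 / interval_h))))
            needed = onset_idx + n_elev + seg2 + 2  # + recovery + one flat draw
            if needed > n_labs:
                extra = needed - n_labs
                for k in range(extra):
                    lab_times.append(
                        lab_times[-1] + timedelta(minutes=int(interval_h * 60))
                    )
                n_labs = needed
                plan = [1.0] * n_labs
            r1 = float(rng.uniform(*STAGE_BANDS[stage]))
            for k in range(onset_idx, onset_idx + n_elev):
                plan[k] = r1
            true_peak = _planted_stage(stage, baseline * r1)
            if seg2:
                r2 = float(rng.uniform(*STAGE_BANDS[peak_stage]))
                for k in range(onset_idx + n_elev, onset_idx + n_elev + seg2):
                    plan[k] = r2
                true_peak = max(true_peak, _planted_stage(peak_stage, baseline * r2))
            recovery_idx = onset_idx + n_elev + seg2
            truth.episodes.append(
                PlantedEpisode(pid, lab_times[onset_idx], true_peak,
                               lab_times[recovery_idx])
            )

        discharge = max(admit + timedelta(hours=stay_h),
                        lab_times[-1] + timedelta(hours=2))
        patient.encounters.append(
            Encounter(f"E{i:04d}", admit, discharge, unit_type, unit_name)
        )
        for t, mult in zip(lab_times, plan):
            patient.labs.append(
                LabResult(pid, Analyte.CREATININE, t, noisy(baseline * mult))
            )
        # companion labs for the dashboard panels
        for t in lab_times[:: max(1, n_labs // 3)]:
            patient.labs.append(LabResult(pid, Analyte.UREA, t, noisy(6.0)))
            patient.labs.append(LabResult(pid, Analyte.SODIUM, t, noisy(139.0)))
            patient.labs.append(LabResult(pid, Analyte.POTASSIUM, t, noisy(4.2)))
            patient.labs.append(LabResult(pid, Analyte.WBC, t, noisy(8.0)))

        onset = truth.episodes[-1].onset_at if has_aki else None
        for cls, p_exposed in config.risk_med_exposure.items():
            if rng.random() < p_exposed:
                drug = _CLASS_AGENTS[cls][int(rng.integers(0, len(_CLASS_AGENTS[cls])))]
                ordered_at = admit + _minutes(rng, 0, stay_h * 0.8)
                disc = None
                if rng.random() < 0.3:
                    disc = ordered_at + _minutes(rng, 24, 72)
                patient.medication_orders.append(
                    MedicationOrder(pid, drug, ordered_at, disc)
                )
                in_window = (
                    onset is not None
                    and onset <= ordered_at <= onset + timedelta(hours=48)
                )
                truth.orders.append(PlantedOrder(pid, drug, cls, in_window))
        if rng.random() < 0.2:
            drug = _RENAL_AGENTS[int(rng.integers(0, len(_RENAL_AGENTS)))]
            patient.medication_orders.append(
                MedicationOrder(pid, drug, admit + _minutes(rng, 0, 24))
            )
            truth.orders.append(PlantedOrder(pid, drug, None, False))
        if rng.random() < 0.3:
            drug = _NEUTRAL_AGENTS[int(rng.integers(0, len(_NEUTRAL_AGENTS)))]
            patient.medication_orders.append(
                MedicationOrder(pid, drug, admit + _minutes(rng, 0, 24))
            )
            truth.orders.append(PlantedOrder(pid, drug, None, False))

        # nursing-shift fluid charting and vitals
        t = admit + timedelta(hours=4)
        while t < discharge:
            patient.fluids.append(
                FluidRecord(pid, FluidKind.INTAKE_IV, round(float(rng.uniform(300, 700))), t)
            )
            patient.fluids.append(
                FluidRecord(pid, FluidKind.OUTPUT_URINE, round(float(rng.uniform(150, 500))), t)
            )
            patient.vitals.append(
                VitalSign(pid, VitalKind.HEART_RATE, round(float(rng.normal(82, 10)), 1), t)
            )
            patient.vitals.append(
                VitalSign(pid, VitalKind.SYSTOLIC_BP, round(float(rng.normal(122, 14)), 1), t)
            )
            patient.vitals.append(
                VitalSign(pid, VitalKind.DIASTOLIC_BP, round(float(rng.normal(72, 9)), 1), t)
            )
            t += timedelta(hours=8)

        patient.sort_events()
        patients.append(patient)

    return Cohort(patients=patients), truth
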