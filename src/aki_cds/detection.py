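"""Creatinine-based AKI detection: baseline selection, KDIGO staging,
and the per-patient alert lifecycle.

Baseline selection follows the NHS England convention: if any
creatinine exists in the 7 days before the index result, the baseline
is the lowest value in that window; otherwise the median of all values
in the preceding year; otherwise no ratio criterion can be evaluated
(absolute criteria still apply).

Staging uses the KDIGO serum-creatinine criteria:

* stage 3 — index/baseline ≥ 3.0, or index ≥ 353.6 µmol/L
* stage 2 — index/baseline ≥ 2.0
* stage 1 — index/baseline ≥ 1.5, or a rise ≥ 26.5 µmol/L above the
  lowest creatinine of the preceding 48 h

Urine-output criteria and renal replacement therapy are deliberately
out of scope: urine-output charting is too variable between wards to
drive automated alerts.

The lifecycle: the first result whose assessment reaches stage ≥ 1
opens an episode and raises an alert; within an episode a new alert is
raised only on progression to a higher stage; a result assessed stage 0
closes the episode (recovery); a later qualifying result opens the next
episode and alerts again. Alerts are never deleted — acknowledgment
only flips their status.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Optional, Sequence

from pydantic import BaseModel, Field, model_validator

from .records import Analyte, LabResult, MedicationOrder, Patient, Setting


class StagingConfig(BaseModel):
    """Thresholds and windows driving detection and medication warnings.

    Numeric defaults are the KDIGO guideline constants, expressed in
    µmol/L; every one is overridable so the same engine can run a
    site-specific variant.
    """

    ratio_stage1: float = 1.5
    ratio_stage2: float = 2.0
    ratio_stage3: float = 3.0
    abs_rise_48h: float = 26.5  # µmol/L over the trailing 48 h
    abs_stage3: float = 353.6  # µmol/L absolute stage-3 threshold
    baseline_short_window_days: int = Field(default=7, gt=0)
    baseline_long_window_days: int = Field(default=365, gt=0)
    #: None disables the upper bound: warn on any risk order during an
    #: open episode.
    med_warning_window_hours: Optional[float] = 48.0
    #: "lowest" (NHS England convention) or "most_recent" within the
    #: short window.
    baseline_short_method: str = "lowest"

    @model_validator(mode="after")
    def _check(self) -> "StagingConfig":
        if not (1.0 < self.ratio_stage1 < self.ratio_stage2 < self.ratio_stage3):
            raise ValueError("require 1 < ratio_stage1 < ratio_stage2 < ratio_stage3")
        if self.abs_rise_48h <= 0 or self.abs_stage3 <= 0:
            raise ValueError("absolute thresholds must be > 0")
        if self.baseline_long_window_days <= self.baseline_short_window_days:
            raise ValueError("long window must exceed short window")
        if self.baseline_short_method not in ("lowest", "most_recent"):
            raise ValueError("baseline_short_method must be 'lowest' or 'most_recent'")
        if self.med_warning_window_hours is not None and self.med_warning_window_hours < 0:
            raise ValueError("med_warning_window_hours must be >= 0")
        return self

    @classmethod
    def from_json_file(cls, path) -> "StagingConfig":
        import json
        from pathlib import Path

        return cls.model_validate(json.loads(Path(path).read_text()))


class BaselineMethod(str, enum.Enum):
    SHORT_WINDOW = "short_window"
    LONG_WINDOW_MEDIAN = "long_window_median"
    UNAVAILABLE = "unavailable"


@dataclass
class BaselineResult:
    method: BaselineMethod
    value: Optional[float]  # µmol/L; None iff method is UNAVAILABLE
    window_start: datetime
    window_end: datetime
    n_contributing: int = 0


@dataclass
class AkiAssessment:
    """Outcome of evaluating one hospital creatinine result."""

    index_result: LabResult
    baseline: BaselineResult
    ratio: Optional[float]  # index / baseline, None when baseline unavailable
    rise_48h: Optional[float]  # index − min(trailing 48 h), None when no prior result
    stage: int  # 0 = no criterion met


class AlertStatus(str, enum.Enum):
    ACTIVE = "active"
    ACKNOWLEDGED = "acknowledged"


@dataclass
class AlertEvent:
    alert_id: str
    patient_id: str
    encounter_id: Optional[str]
    stage: int
    raised_at: datetime
    assessment: AkiAssessment
    active_risk_medications: list[MedicationOrder] = field(default_factory=list)
    status: AlertStatus = AlertStatus.ACTIVE
    acknowledged_at: Optional[datetime] = None
    episode_index: int = 1


@dataclass
class EpisodeState:
    """Mutable lifecycle state carried between creatinine results."""

    patient_id: str
    episode_index: int = 0
    in_episode: bool = False
    onset_at: Optional[datetime] = None
    max_alerted_stage: int = 0


@dataclass
class Episode:
    """One contiguous AKI event from onset to recovery (or stream end)."""

    patient_id: str
    episode_index: int
    onset_at: datetime
    closed_at: Optional[datetime]  # recovery result time; None if still open
    alerts: list[AlertEvent] = field(default_factory=list)

    @property
    def max_stage(self) -> int:
        return max(a.stage for a in self.alerts)

    def open_at(self, at: datetime) -> bool:
        """Episode is open on [onset_at, closed_at)."""
        if at < self.onset_at:
            return False
        return self.closed_at is None or at < self.closed_at

    def stage_at(self, at: datetime) -> int:
        """Highest stage alerted at or before ``at`` within this episode."""
        return max((a.stage for a in self.alerts if a.raised_at <= at), default=0)


@dataclass
class DetectionResult:
    alerts: list[AlertEvent]
    episodes: list[Episode]
    final_state: EpisodeState


def compute_baseline(
    creatinine_history: Sequence[LabResult],
    index_time: datetime,
    config: StagingConfig,
) -> BaselineResult:
    """Select the baseline creatinine for an index result at ``index_time``.

    ``creatinine_history`` must hold only creatinine results collected
    strictly before ``index_time`` (the index result never contributes
    to its own baseline). Community and hospital results are both
    eligible. Windows are half-open: the short window is
    ``(index_time − 7 d, index_time)``; the long window is
    ``(index_time − 365 d, index_time − 7 d]``.
    """
    for r in creatinine_history:
        if r.analyte is not Analyte.CREATININE:
            raise ValueError("baseline history must contain only creatinine results")
        if r.collected_at >= index_time:
            raise ValueError("baseline history must precede the index time")
    short_start = index_time - timedelta(days=config.baseline_short_window_days)
    long_start = index_time - timedelta(days=config.baseline_long_window_days)

    short = [r for r in creatinine_history if short_start < r.collected_at < index_time]
    if short:
        if config.baseline_short_method == "lowest":
            value = min(r.value for r in short)
        else:
            value = short[-1].value  # history is time-sorted
        return BaselineResult(
            BaselineMethod.SHORT_WINDOW, value, short_start, index_time, len(short)
        )
    long = [r for r in creatinine_history if long_start < r.collected_at <= short_start]
    if long:
        # even count → arithmetic mean of the two middle values
        value = statistics.median(r.value for r in long)
        return BaselineResult(
            BaselineMethod.LONG_WINDOW_MEDIAN, value, long_start, short_start, len(long)
        )
    return BaselineResult(BaselineMethod.UNAVAILABLE, None, long_start, index_time, 0)


def stage_aki(
    index: LabResult,
    baseline: BaselineResult,
    recent_48h: Sequence[LabResult],
    config: StagingConfig,
) -> AkiAssessment:
    """Stage one creatinine result against its baseline.

    ``recent_48h`` holds the creatinine results in the half-open window
    ``(index time − 48 h, index time)``, used for the stage-1 absolute
    rise criterion. When the baseline is unavailable the ratio criteria
    are skipped but the absolute criteria still apply.
    """
    if index.analyte is not Analyte.CREATININE:
        raise ValueError(f"stage_aki requires a creatinine result, got {index.analyte.value}")
    ratio = None
    if baseline.value is not None:
        ratio = index.value / baseline.value
    rise = None
    if recent_48h:
        rise = index.value - min(r.value for r in recent_48h)

    if (ratio is not None and ratio >= config.ratio_stage3) or index.value >= config.abs_stage3:
        stage = 3
    elif ratio is not None and ratio >= config.ratio_stage2:
        stage = 2
    elif (ratio is not None and ratio >= config.ratio_stage1) or (
        rise is not None and rise >= config.abs_rise_48h
    ):
        stage = 1
    else:
        stage = 0
    return AkiAssessment(index, baseline, ratio, rise, stage)


def assess_result(
    patient: Patient, index: LabResult, config: StagingConfig
) -> AkiAssessment:
    """Assess one hospital creatinine result using the patient's full
    prior history (both baseline windows and the 48-h rise window)."""
    history = [
        r for r in patient.creatinine() if r.collected_at < index.collected_at
    ]
    recent_start = index.collected_at - timedelta(hours=48)
    recent = [r for r in history if recent_start < r.collected_at]
    baseline = compute_baseline(history, index.collected_at, config)
    return stage_aki(index, baseline, recent, config)


def detect(
    patient: Patient,
    config: Optional[StagingConfig] = None,
    formulary=None,
) -> DetectionResult:
    """Run the alert lifecycle over one patient's event stream.

    Each hospital creatinine result is evaluated in arrival order with
    the baseline recomputed from all prior results. Alerts carry the
    patient's active AKI-risk medications at the moment the alert is
    raised (an empty list when no formulary is supplied).
    """
    from .medsafety import Formulary, active_risk_medications

    config = config or StagingConfig()
    if formulary is None:
        formulary = Formulary.default()
    state = EpisodeState(patient_id=patient.patient_id)
    alerts: list[AlertEvent] = []
    episodes: list[Episode] = []
    current: Optional[Episode] = None

    for index in patient.creatinine():
        if index.setting is not Setting.HOSPITAL:
            continue
        assessment = assess_result(patient, index, config)
        if not state.in_episode:
            if assessment.stage >= 1:
                state.in_episode = True
                state.episode_index += 1
                state.onset_at = index.collected_at
                state.max_alerted_stage = assessment.stage
                current = Episode(
                    patient.patient_id, state.episode_index, index.collected_at, None
                )
                episodes.append(current)
                alert = _make_alert(patient, index, assessment, state, formulary)
                alerts.append(alert)
                current.alerts.append(alert)
        else:
            if assessment.stage == 0:
                # recovery closes the episode at this result's time
                state.in_episode = False
                state.onset_at = None
                assert current is not None
                current.closed_at = index.collected_at
                current = None
                state.max_alerted_stage = 0
            elif assessment.stage > state.max_alerted_stage:
                state.max_alerted_stage = assessment.stage
                alert = _make_alert(patient, index, assessment, state, formulary)
                alerts.append(alert)
                assert current is not None
                current.alerts.append(alert)
            # de-escalation within an episode: no alert, no state change
    return DetectionResult(alerts, episodes, state)


def _make_alert(patient, index, assessment, state, formulary) -> AlertEvent:
    from .medsafety import active_risk_medications

    enc = patient.encounter_at(index.collected_at)
    return AlertEvent(
        alert_id=f"{patient.patient_id}-e{state.episode_index}-s{assessment.stage}",
        patient_id=patient.patient_id,
        encounter_id=enc.encounter_id if enc else None,
        stage=assessment.stage,
        raised_at=index.collected_at,
        assessment=assessment,
        active_risk_medications=active_risk_medications(
            patient.medication_orders, index.collected_at, formulary
        ),
        episode_index=state.episode_index,
    )


def process_patient(
    patient: Patient,
    config: Optional[StagingConfig] = None,
    formulary=None,
) -> tuple[list[AlertEvent], EpisodeState]:
    """Alert list and final lifecycle state for one patient."""
    result = detect(patient, config, formulary)
    return result.alerts, result.final_state


def acknowledge_alert(alert: AlertEvent, at: datetime) -> AlertEvent:
    """Acknowledge an alert; idempotent on an already-acknowledged one.

    The alert stays in the permanent history — acknowledgment only
    removes it from the front-screen display, so here it only flips the
    status field.
    """
    if alert.status is AlertStatus.ACKNOWLEDGED:
        return alert
    if at < alert.raised_at:
        raise ValueError("cannot acknowledge an alert before it was raised")
    return replace(alert, status=AlertStatus.ACKNOWLEDGED, acknowledged_at=at)
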