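"""Shared fixtures and independent oracles for the test suite.

The oracles re-derive detection outcomes by a different route than the
engine (full-history recomputation with bisect-based window slicing and
episode segmentation of the per-result stage sequence) so the streaming
state machine can be checked against them on arbitrary cohorts.
"""

from __future__ import annotations

import bisect
from datetime import datetime, timedelta

import pytest

from aki_cds import (
    Analyte,
    Cohort,
    Encounter,
    Formulary,
    LabResult,
    MedicationOrder,
    Patient,
    Setting,
    StagingConfig,
    UnitType,
    utc,
)

T0 = utc(2025, 3, 10, 8, 0)


@pytest.fixture(scope="session")
def config() -> StagingConfig:
    return StagingConfig()


@pytest.fixture(scope="session")
def formulary() -> Formulary:
    return Formulary.default()


def make_patient(
    pid: str = "P1",
    creatinine: list[tuple[datetime, float, Setting]] = (),
    orders: list[MedicationOrder] = (),
    unit: UnitType = UnitType.MEDICAL,
) -> Patient:
    """A one-encounter patient with the given creatinine history."""
    p = Patient(patient_id=pid)
    p.encounters.append(
        Encounter(f"E-{pid}", T0 - timedelta(hours=6), T0 + timedelta(days=10), unit, "U1")
    )
    for at, value, setting in creatinine:
        p.labs.append(LabResult(pid, Analyte.CREATININE, at, value, setting=setting))
    p.medication_orders = list(orders)
    p.sort_events()
    return p


# ---------------------------------------------------------------------------
# independent oracles


def oracle_stage(
    value: float,
    baseline: float | None,
    min_recent_48h: float | None,
    cfg: StagingConfig,
) -> int:
    """Threshold evaluator written as a flat scan over the criteria."""
    met = set()
    if value >= cfg.abs_stage3:
        met.add(3)
    if baseline is not None:
        r = value / baseline
        for stage, thr in ((1, cfg.ratio_stage1), (2, cfg.ratio_stage2), (3, cfg.ratio_stage3)):
            if r >= thr:
                met.add(stage)
    if min_recent_48h is not None and value - min_recent_48h >= cfg.abs_rise_48h:
        met.add(1)
    return max(met, default=0)


def oracle_assess_all(patient: Patient, cfg: StagingConfig):
    """Independently assess every hospital creatinine result.

    Returns a list of (result, stage) in time order, recomputing
    baseline and 48-h windows from the full sorted history with bisect.
    """
    creat = sorted(patient.creatinine(), key=lambda r: r.collected_at)
    times = [r.collected_at for r in creat]
    out = []
    for i, r in enumerate(creat):
        if r.setting is not Setting.HOSPITAL:
            continue
        t = r.collected_at
        lo = bisect.bisect_right(times, t - timedelta(days=cfg.baseline_short_window_days))
        hi = bisect.bisect_left(times, t)
        short = [creat[j].value for j in range(lo, hi) if creat[j].collected_at < t]
        if short:
            baseline = min(short) if cfg.baseline_short_method == "lowest" else short[-1]
        else:
            llo = bisect.bisect_right(times, t - timedelta(days=cfg.baseline_long_window_days))
            longvals = sorted(
                creat[j].value
                for j in range(llo, hi)
                if creat[j].collected_at <= t - timedelta(days=cfg.baseline_short_window_days)
            )
            if longvals:
                n = len(longvals)
                baseline = (
                    longvals[n // 2]
                    if n % 2
                    else (longvals[n // 2 - 1] + longvals[n // 2]) / 2
                )
            else:
                baseline = None
        rlo = bisect.bisect_right(times, t - timedelta(hours=48))
        recent = [creat[j].value for j in range(rlo, hi) if creat[j].collected_at < t]
        min_recent = min(recent) if recent else None
        out.append((r, oracle_stage(r.value, baseline, min_recent, cfg)))
    return out


def oracle_alerts(patient: Patient, cfg: StagingConfig):
    """Segment the per-result stage sequence into episodes and derive
    the expected (stage, episode_index, raised_at) alert list."""
    alerts = []
    episodes = []  # (onset, closed_or_None, [(stage, raised_at)])
    episode = 0
    max_stage = 0
    onset = None
    for r, stage in oracle_assess_all(patient, cfg):
        if onset is None:
            if stage >= 1:
                episode += 1
                onset = r.collected_at
                max_stage = stage
                episodes.append([onset, None, [(stage, r.collected_at)]])
                alerts.append((stage, episode, r.collected_at))
        else:
            if stage == 0:
                episodes[-1][1] = r.collected_at
                onset = None
                max_stage = 0
            elif stage > max_stage:
                max_stage = stage
                episodes[-1][2].append((stage, r.collected_at))
                alerts.append((stage, episode, r.collected_at))
    return alerts, episodes


def oracle_warning_pairs(patient: Patient, cfg: StagingConfig, formulary: Formulary):
    """Brute-force enumeration of (order, episode) pairs satisfying the
    warning rule; returns (drug_name, ordered_at, stage_at_order) tuples."""
    _, episodes = oracle_alerts(patient, cfg)
    pairs = []
    for order in patient.medication_orders:
        if not formulary.lookup(order.drug_name).may_cause_aki:
            continue
        for onset, closed, stage_alerts in episodes:
            t = order.ordered_at
            if t < onset or (closed is not None and t >= closed):
                continue
            if cfg.med_warning_window_hours is not None and t > onset + timedelta(
                hours=cfg.med_warning_window_hours
            ):
                continue
            stage = max(s for s, at in stage_alerts if at <= t)
            pairs.append((order.drug_name, t, stage))
    pairs.sort(key=lambda p: p[1])
    return pairs
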