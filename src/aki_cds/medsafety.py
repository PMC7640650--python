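"""Formulary-driven AKI medication safety.

Identifies active medications that can worsen kidney function
(diuretics, nephrotoxic antibiotics, ACE inhibitors / angiotensin
receptor blockers, NSAIDs) or that are renally cleared, and raises an
interruptive warning when a risk medication is ordered within 48 h of
AKI onset. The warning never blocks the order — the prescriber can
always override, and the warning is recorded either way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from .detection import Episode, EpisodeState, StagingConfig
from .records import DrugClass, MedicationOrder, Patient


@dataclass(frozen=True)
class RiskProfile:
    risk_class: DrugClass
    may_cause_aki: bool = False
    renally_cleared: bool = False


_UNKNOWN = RiskProfile(DrugClass.OTHER, False, False)


def normalize_drug_name(name: str) -> str:
    return name.strip().casefold()


class Formulary:
    """Mapping from normalized drug name to its AKI risk profile.

    Lookup is total: unknown names resolve to class ``other`` with both
    flags false. The shipped default lists representative agents per
    class and is meant to be replaced with a site formulary.
    """

    def __init__(self, entries: dict[str, RiskProfile]):
        self.entries = {normalize_drug_name(k): v for k, v in entries.items()}
        for name, prof in self.entries.items():
            if not (prof.may_cause_aki or prof.renally_cleared):
                raise ValueError(
                    f"formulary entry {name!r} has no true flag; omit it instead"
                )

    def lookup(self, drug_name: str) -> RiskProfile:
        return self.entries.get(normalize_drug_name(drug_name), _UNKNOWN)

    @classmethod
    def from_json_file(cls, path: str | Path) -> "Formulary":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls._from_dict(data)

    @classmethod
    def _from_dict(cls, data: dict) -> "Formulary":
        entries = {}
        for name, spec in data["entries"].items():
            entries[name] = RiskProfile(
                risk_class=DrugClass(spec["risk_class"]),
                may_cause_aki=bool(spec.get("may_cause_aki", False)),
                renally_cleared=bool(spec.get("renally_cleared", False)),
            )
        return cls(entries)

    @classmethod
    def default(cls) -> "Formulary":
        raw = (
            resources.files("aki_cds").joinpath("data/formulary.json").read_text("utf-8")
        )
        return cls._from_dict(json.loads(raw))


@dataclass
class MedicationWarning:
    warning_id: str
    patient_id: str
    order: MedicationOrder
    aki_stage_at_order: int
    onset_at: datetime
    raised_at: datetime  # equals order.ordered_at
    overridden: bool = False


def classify_medication(drug_name: str, formulary: Formulary) -> RiskProfile:
    """Deterministic class + flags for a free-text drug name."""
    return formulary.lookup(drug_name)


def annotate_orders(orders: Sequence[MedicationOrder], formulary: Formulary) -> None:
    """Fill each order's ``drug_class`` from the formulary, in place."""
    for o in orders:
        o.drug_class = formulary.lookup(o.drug_name).risk_class


def active_risk_medications(
    orders: Sequence[MedicationOrder], at: datetime, formulary: Formulary
) -> list[MedicationOrder]:
    """Orders active at ``at`` (ordered_at ≤ at < discontinued_at) whose
    formulary profile says they may cause AKI; stable order by
    ordered_at."""
    out = []
    for o in orders:
        if o.active_at(at) and formulary.lookup(o.drug_name).may_cause_aki:
            o.drug_class = formulary.lookup(o.drug_name).risk_class
            out.append(o)
    out.sort(key=lambda o: o.ordered_at)
    return out


def _in_warning_window(
    ordered_at: datetime, onset_at: datetime, config: StagingConfig
) -> bool:
    # window is closed at both ends: onset ≤ order ≤ onset + 48 h
    if ordered_at < onset_at:
        return False
    if config.med_warning_window_hours is None:
        return True
    return ordered_at <= onset_at + timedelta(hours=config.med_warning_window_hours)


def check_medication_order(
    order: MedicationOrder,
    episode: EpisodeState,
    formulary: Formulary,
    config: Optional[StagingConfig] = None,
) -> Optional[MedicationWarning]:
    """Evaluate one order against the patient's lifecycle state at order
    time.

    A warning is returned iff an episode is open, the order falls
    within the post-onset window, and the drug may cause AKI. The
    warning records the highest stage alerted so far in the episode.
    """
    config = config or StagingConfig()
    if not episode.in_episode or episode.onset_at is None:
        return None
    if not _in_warning_window(order.ordered_at, episode.onset_at, config):
        return None
    profile = formulary.lookup(order.drug_name)
    if not profile.may_cause_aki:
        return None
    order.drug_class = profile.risk_class
    return MedicationWarning(
        warning_id=f"{order.patient_id}-w-{order.drug_name}-{order.ordered_at.isoformat()}",
        patient_id=order.patient_id,
        order=order,
        aki_stage_at_order=episode.max_alerted_stage,
        onset_at=episode.onset_at,
        raised_at=order.ordered_at,
    )


def generate_warnings(
    patient: Patient,
    episodes: Sequence[Episode],
    formulary: Formulary,
    config: Optional[StagingConfig] = None,
) -> list[MedicationWarning]:
    """All warnings a patient's order stream would have triggered,
    replayed against the detected episode timeline."""
    config = config or StagingConfig()
    warnings: list[MedicationWarning] = []
    for order in patient.medication_orders:
        for ep in episodes:
            if not ep.open_at(order.ordered_at):
                continue
            state = EpisodeState(
                patient_id=patient.patient_id,
                episode_index=ep.episode_index,
                in_episode=True,
                onset_at=ep.onset_at,
                max_alerted_stage=ep.stage_at(order.ordered_at),
            )
            warning = check_medication_order(order, state, formulary, config)
            if warning is not None:
                warnings.append(warning)
            break  # episodes never overlap
    warnings.sort(key=lambda w: w.raised_at)
    return warnings
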