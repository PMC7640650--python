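"""Volume-status-branched AKI order-set recommendations.

The engine mirrors the structure of an institutional AKI order set:
investigations, exactly one fluid strategy chosen by the clinical
volume-status assessment (bolus for hypovolemia, maintenance fluids
for euvolemia, diuretics for hypervolemia), mandatory monitoring
safety parameters whenever a bolus is recommended, per-drug review
suggestions for active AKI-risk medications, and consult guidance.
Item wording lives in an editable JSON template; the engine enforces
only the structure.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from .medsafety import Formulary
from .records import MedicationOrder


class VolumeStatus(str, enum.Enum):
    HYPOVOLEMIC = "hypovolemic"
    EUVOLEMIC = "euvolemic"
    HYPERVOLEMIC = "hypervolemic"


@dataclass
class ClinicalAssessmentInput:
    """Bedside assessment flags that branch the order set."""

    volume_status: VolumeStatus
    overload_risk: bool = False  # risk of developing volume overload
    obstruction_suspected: bool = False
    wants_pharmacy_support: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.volume_status, VolumeStatus):
            self.volume_status = VolumeStatus(self.volume_status)


@dataclass
class OrderRecommendation:
    investigations: list[str] = field(default_factory=list)
    fluid_plan: list[str] = field(default_factory=list)
    monitoring: list[str] = field(default_factory=list)
    medication_actions: list[str] = field(default_factory=list)
    consults: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "investigations": self.investigations,
            "fluid_plan": self.fluid_plan,
            "monitoring": self.monitoring,
            "medication_actions": self.medication_actions,
            "consults": self.consults,
        }


def load_order_set_template(path: Optional[str | Path] = None) -> dict:
    if path is not None:
        return json.loads(Path(path).read_text(encoding="utf-8"))
    raw = resources.files("aki_cds").joinpath("data/order_set_template.json").read_text("utf-8")
    return json.loads(raw)


def recommend_orders(
    assessment: ClinicalAssessmentInput,
    active_risk_meds: Sequence[MedicationOrder] = (),
    template: Optional[dict] = None,
    formulary: Optional[Formulary] = None,
) -> OrderRecommendation:
    """Deterministic order recommendation for one assessment.

    Exactly one fluid-strategy branch is active; a bolus plan always
    comes with monitoring safety parameters to catch developing volume
    overload during resuscitation.
    """
    template = template or load_order_set_template()
    formulary = formulary or Formulary.default()
    rec = OrderRecommendation()

    rec.investigations = list(template["investigations"]["base"])
    if assessment.obstruction_suspected:
        rec.investigations += template["investigations"]["obstruction"]

    status = assessment.volume_status
    rec.fluid_plan = list(template["fluid_plans"][status.value])
    if status is VolumeStatus.HYPOVOLEMIC:
        rec.monitoring = list(template["monitoring"]["bolus"])
        if assessment.overload_risk:
            rec.monitoring += template["monitoring"]["overload_risk"]

    action = template["medication_action"]
    for order in active_risk_meds:
        cls = order.drug_class or formulary.lookup(order.drug_name).risk_class
        rec.medication_actions.append(
            action.format(drug_name=order.drug_name, drug_class=cls.value)
        )

    rec.consults = list(template["consults"]["nephrology_criteria"])
    if assessment.wants_pharmacy_support:
        rec.consults.append(template["consults"]["pharmacy"])

    if not rec.fluid_plan:
        raise ValueError("template provides no fluid plan for " + status.value)
    if status is VolumeStatus.HYPOVOLEMIC and not rec.monitoring:
        raise ValueError("bolus recommendation requires monitoring items")
    return rec
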