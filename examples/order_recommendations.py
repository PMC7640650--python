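"""Volume-status-branched order-set recommendations.

A hypovolemic patient at risk of volume overload gets an IV bolus plan
with mandatory monitoring safety parameters; active risk medications
get per-drug review suggestions.
"""

from aki_cds import (
    ClinicalAssessmentInput, MedicationOrder, VolumeStatus, recommend_orders, utc,
)

rec = recommend_orders(
    ClinicalAssessmentInput(
        volume_status=VolumeStatus.HYPOVOLEMIC,
        overload_risk=True,
        obstruction_suspected=True,
        wants_pharmacy_support=True,
    ),
    active_risk_meds=[
        MedicationOrder("demo", "ibuprofen", utc(2025, 3, 10)),
        MedicationOrder("demo", "ramipril", utc(2025, 3, 10)),
    ],
)
for section, items in rec.to_dict().items():
    print(f"{section}:")
    for item in items:
        print(f"  - {item}")
# Exactly one fluid strategy is active (bolus, because hypovolemic);
# monitoring is never empty when a bolus is recommended.
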