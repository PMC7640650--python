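"""Interruptive warnings for nephrotoxins ordered within 48 h of AKI onset.

Ibuprofen ordered 24 h after onset triggers a warning; the same drug at
60 h does not (outside the window), and acetaminophen never does (not a
risk medication).
"""

from datetime import timedelta

from aki_cds import (
    Analyte, Encounter, Formulary, LabResult, MedicationOrder, Patient,
    Setting, UnitType, detect, generate_warnings, utc,
)

t = utc(2025, 3, 10, 8)
p = Patient("demo")
p.encounters.append(Encounter("E1", t - timedelta(hours=6), t + timedelta(days=7),
                              UnitType.SURGICAL, "Surg-1"))
p.labs += [
    LabResult("demo", Analyte.CREATININE, t - timedelta(days=2), 100, setting=Setting.COMMUNITY),
    LabResult("demo", Analyte.CREATININE, t, 165, setting=Setting.HOSPITAL),
]
p.medication_orders += [
    MedicationOrder("demo", "ibuprofen", t + timedelta(hours=24)),
    MedicationOrder("demo", "ibuprofen", t + timedelta(hours=60)),
    MedicationOrder("demo", "acetaminophen", t + timedelta(hours=24)),
]
p.sort_events()

formulary = Formulary.default()
result = detect(p, formulary=formulary)
warnings = generate_warnings(p, result.episodes, formulary)
for w in warnings:
    print(f"warning: {w.order.drug_name} ({w.order.drug_class.value}) ordered "
          f"{(w.raised_at - w.onset_at).total_seconds()/3600:.0f} h after onset, "
          f"AKI stage {w.aki_stage_at_order}")
print(f"{len(warnings)} warning(s) from {len(p.medication_orders)} orders")
# Only the in-window risk order warns; the warning is interruptive but
# overridable, so it records the order rather than blocking it.
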