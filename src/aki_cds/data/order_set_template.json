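{
  "description": "Editable order-set content. Item wording is institutional; the engine enforces structure only (exactly one fluid-strategy branch; monitoring whenever a bolus is recommended). Bolus parameters (fluid type, volume, rate) are placeholders the prescriber completes.",
  "investigations": {
    "base": [
      "Serum creatinine and urea, repeat in 12-24 h",
      "Electrolytes (sodium, potassium, bicarbonate)",
      "Urinalysis with microscopy",
      "Urine protein quantification",
      "Complete blood count"
    ],
    "obstruction": [
      "Renal tract ultrasound (kidney, ureter, bladder) — consider when urinary tract obstruction is suspected; see clinical guidance on indications for ultrasonography"
    ]
  },
  "fluid_plans": {
    "hypovolemic": [
      "IV fluid bolus: [fluid type] [volume] mL over [duration] — reassess volume status after administration",
      "Repeat bolus per reassessment; define stop criteria before starting"
    ],
    "euvolemic": [
      "Maintenance IV fluids: [fluid type] at [rate] mL/h",
      "Reassess volume status and ongoing fluid needs every 12-24 h"
    ],
    "hypervolemic": [
      "Diuretic therapy: [agent] [dose] [route] — review response with urine output and daily weight",
      "Restrict fluid intake; reassess volume status every 12-24 h"
    ]
  },
  "monitoring": {
    "bolus": [
      "Vital signs including respiratory rate and oxygen saturation after each bolus",
      "Strict intake/output charting",
      "Reassess for signs of volume overload (new dyspnea, crackles, rising oxygen requirement) after each bolus"
    ],
    "overload_risk": [
      "Daily weight",
      "Limit individual bolus volume; reassess between boluses before continuing"
    ]
  },
  "medication_action": "Review and consider holding {drug_name} ({drug_class}) while AKI is ongoing",
  "consults": {
    "nephrology_criteria": [
      "Nephrology consultation if stage 3 AKI, no identifiable cause, or no improvement within 48-72 h of initial management",
      "Urology consultation if obstruction confirmed on imaging"
    ],
    "pharmacy": "Pharmacy consultation for medication review and renal dose adjustment"
  }
}
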