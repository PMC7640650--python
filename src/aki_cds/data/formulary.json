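{
  "description": "Synthetic default formulary with representative agents per AKI-risk class. The deployed provincial formulary is institution-specific; replace this file with a site formulary for production use. Classes: diuretic, antibiotic (nephrotoxic), acei_arb (ACE inhibitors / angiotensin receptor blockers), nsaid. Drugs that are renally cleared carry the renally_cleared flag and may additionally belong to a risk class.",
  "entries": {
    "furosemide": {"risk_class": "diuretic", "may_cause_aki": true},
    "hydrochlorothiazide": {"risk_class": "diuretic", "may_cause_aki": true},
    "metolazone": {"risk_class": "diuretic", "may_cause_aki": true},
    "spironolactone": {"risk_class": "diuretic", "may_cause_aki": true},
    "indapamide": {"risk_class": "diuretic", "may_cause_aki": true},
    "gentamicin": {"risk_class": "antibiotic", "may_cause_aki": true, "renally_cleared": true},
    "tobramycin": {"risk_class": "antibiotic", "may_cause_aki": true, "renally_cleared": true},
    "amikacin": {"risk_class": "antibiotic", "may_cause_aki": true, "renally_cleared": true},
    "vancomycin": {"risk_class": "antibiotic", "may_cause_aki": true, "renally_cleared": true},
    "ramipril": {"risk_class": "acei_arb", "may_cause_aki": true},
    "perindopril": {"risk_class": "acei_arb", "may_cause_aki": true},
    "lisinopril": {"risk_class": "acei_arb", "may_cause_aki": true},
    "enalapril": {"risk_class": "acei_arb", "may_cause_aki": true},
    "candesartan": {"risk_class": "acei_arb", "may_cause_aki": true},
    "valsartan": {"risk_class": "acei_arb", "may_cause_aki": true},
    "losartan": {"risk_class": "acei_arb", "may_cause_aki": true},
    "irbesartan": {"risk_class": "acei_arb", "may_cause_aki": true},
    "ibuprofen": {"risk_class": "nsaid", "may_cause_aki": true},
    "naproxen": {"risk_class": "nsaid", "may_cause_aki": true},
    "ketorolac": {"risk_class": "nsaid", "may_cause_aki": true},
    "celecoxib": {"risk_class": "nsaid", "may_cause_aki": true},
    "diclofenac": {"risk_class": "nsaid", "may_cause_aki": true},
    "indomethacin": {"risk_class": "nsaid", "may_cause_aki": true},
    "digoxin": {"risk_class": "renally_cleared", "renally_cleared": true},
    "metformin": {"risk_class": "renally_cleared", "renally_cleared": true},
    "enoxaparin": {"risk_class": "renally_cleared", "renally_cleared": true},
    "gabapentin": {"risk_class": "renally_cleared", "renally_cleared": true},
    "morphine": {"risk_class": "renally_cleared", "renally_cleared": true},
    "allopurinol": {"risk_class": "renally_cleared", "renally_cleared": true}
  }
}
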