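{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "AKI risk formulary",
  "description": "Mapping from drug name (normalized by trimming and case-folding at load time) to its AKI risk profile. Every entry must set at least one flag; unknown names resolve to class 'other' with both flags false.",
  "type": "object",
  "required": ["entries"],
  "properties": {
    "description": {"type": "string"},
    "entries": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["risk_class"],
        "properties": {
          "risk_class": {"enum": ["diuretic", "antibiotic", "acei_arb", "nsaid", "renally_cleared", "other"]},
          "may_cause_aki": {"type": "boolean", "default": false},
          "renally_cleared": {"type": "boolean", "default": false}
        }
      }
    }
  }
}
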