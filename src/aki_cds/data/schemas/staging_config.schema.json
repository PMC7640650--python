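{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "AKI staging configuration",
  "description": "Thresholds and windows for creatinine-based AKI staging and medication warnings. Defaults are the KDIGO guideline constants in µmol/L.",
  "type": "object",
  "properties": {
    "ratio_stage1": {"type": "number", "exclusiveMinimum": 1, "default": 1.5},
    "ratio_stage2": {"type": "number", "default": 2.0},
    "ratio_stage3": {"type": "number", "default": 3.0},
    "abs_rise_48h": {"type": "number", "exclusiveMinimum": 0, "default": 26.5},
    "abs_stage3": {"type": "number", "exclusiveMinimum": 0, "default": 353.6},
    "baseline_short_window_days": {"type": "integer", "exclusiveMinimum": 0, "default": 7},
    "baseline_long_window_days": {"type": "integer", "exclusiveMinimum": 0, "default": 365},
    "med_warning_window_hours": {"type": ["number", "null"], "minimum": 0, "default": 48, "description": "null disables the upper bound (warn any time during an open episode)"},
    "baseline_short_method": {"enum": ["lowest", "most_recent"], "default": "lowest"}
  },
  "additionalProperties": false
}
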