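{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Patient event stream record",
  "description": "One row of a CSV event stream or one object of a JSONL stream. record_kind discriminates the payload; timestamps are ISO-8601 (naive values are taken as UTC); creatinine values are in µmol/L unless the reader is told mg/dL.",
  "type": "object",
  "required": ["record_kind", "patient_id", "timestamp"],
  "properties": {
    "record_kind": {"enum": ["encounter", "lab", "med_order", "fluid", "vital"]},
    "patient_id": {"type": "string", "minLength": 1},
    "encounter_id": {"type": "string"},
    "timestamp": {"type": "string", "format": "date-time"},
    "analyte": {"enum": ["creatinine", "urea", "sodium", "potassium", "bicarbonate", "wbc", "urinalysis", "urine_protein", "other"]},
    "value": {"type": "number"},
    "text": {"type": "string"},
    "setting": {"enum": ["hospital", "community"]},
    "drug_name": {"type": "string"},
    "discontinued_at": {"type": "string", "format": "date-time"},
    "fluid_kind": {"enum": ["intake_iv", "intake_oral", "output_urine", "output_other"]},
    "volume": {"type": "number", "minimum": 0},
    "vital_kind": {"enum": ["heart_rate", "systolic_bp", "diastolic_bp"]},
    "unit_type": {"enum": ["medical", "surgical"]},
    "unit_name": {"type": "string"},
    "discharge_time": {"type": "string", "format": "date-time"}
  },
  "allOf": [
    {"if": {"properties": {"record_kind": {"const": "lab"}}}, "then": {"required": ["analyte"]}},
    {"if": {"properties": {"record_kind": {"const": "med_order"}}}, "then": {"required": ["drug_name"]}},
    {"if": {"properties": {"record_kind": {"const": "fluid"}}}, "then": {"required": ["fluid_kind", "volume"]}},
    {"if": {"properties": {"record_kind": {"const": "vital"}}}, "then": {"required": ["vital_kind", "value"]}}
  ]
}
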