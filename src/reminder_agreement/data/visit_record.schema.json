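{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://example.org/reminder-agreement/visit_record.schema.json",
  "title": "PatientVisitRecord",
  "description": "One line of a visit-record JSON-Lines cohort file: the chart snapshot visible to the rule engines for a single patient visit. All dates are ISO-8601 calendar dates and must not be after visit_date.",
  "type": "object",
  "required": ["visit_id", "patient_id", "visit_date", "events"],
  "additionalProperties": false,
  "properties": {
    "visit_id": {"type": "string", "minLength": 1},
    "patient_id": {"type": "string", "minLength": 1},
    "visit_date": {"type": "string", "format": "date"},
    "events": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["kind", "system", "code", "date"],
        "additionalProperties": false,
        "properties": {
          "kind": {"enum": ["problem", "lab", "medication", "exam", "discharge_dx"]},
          "system": {"type": "string", "minLength": 1},
          "code": {"type": "string", "minLength": 1},
          "display": {"type": "string"},
          "date": {"type": "string", "format": "date"},
          "value": {"type": "number"}
        }
      }
    }
  }
}
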