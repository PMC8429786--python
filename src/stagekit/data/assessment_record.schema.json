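{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/stagekit/assessment_record.schema.json",
  "title": "stagekit assessment records (JSON input format)",
  "description": "A list of person-occasion assessment objects: item-level QIDS-SR16 / PHQ-9 responses, clinical flags, and a social/occupational functioning rating.",
  "type": "array",
  "items": {
    "type": "object",
    "required": ["person_id", "occasion"],
    "additionalProperties": false,
    "properties": {
      "person_id": {"type": "string", "minLength": 1},
      "occasion": {"type": "string", "format": "date"},
      "scales": {
        "type": "object",
        "additionalProperties": false,
        "properties": {
          "qids_sr16": {
            "type": "array",
            "minItems": 1,
            "maxItems": 16,
            "items": {"type": ["integer", "null"], "minimum": 0, "maximum": 3}
          },
          "phq9": {
            "type": "array",
            "minItems": 1,
            "maxItems": 9,
            "items": {"type": ["integer", "null"], "minimum": 0, "maximum": 3}
          }
        }
      },
      "flags": {
        "type": "object",
        "additionalProperties": false,
        "properties": {
          "hypomania": {"$ref": "#/$defs/ordinal"},
          "psychosis": {"$ref": "#/$defs/ordinal"},
          "comorbidity": {"$ref": "#/$defs/ordinal"},
          "substance_misuse": {"$ref": "#/$defs/ordinal"},
          "severe_suicidality": {"type": "boolean"},
          "hospitalization_history": {"type": "boolean"},
          "course_flag": {"type": "boolean"},
          "manic_syndrome": {"type": "boolean"},
          "psychotic_syndrome": {"type": "boolean"},
          "severe_anxiety_syndrome": {"type": "boolean"},
          "specific_severe_anxiety": {"type": "boolean"}
        }
      },
      "functioning": {
        "type": "object",
        "additionalProperties": false,
        "properties": {
          "band": {
            "type": ["string", "null"],
            "enum": ["none_mild", "moderate_severe", "major_ongoing", null]
          },
          "score": {"type": ["number", "null"], "minimum": 0, "maximum": 100}
        }
      }
    }
  },
  "$defs": {
    "ordinal": {"type": "string", "enum": ["none", "possible", "probable"]}
  }
}
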