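{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Criterion mapping",
  "type": "object",
  "required": ["entries"],
  "additionalProperties": false,
  "properties": {
    "entries": {"type": "array", "items": {"$ref": "#/$defs/entry"}}
  },
  "$defs": {
    "termCode": {
      "type": "object",
      "required": ["system", "code"],
      "properties": {
        "system": {"type": "string", "minLength": 1},
        "code": {"type": "string", "minLength": 1},
        "display": {"type": "string"},
        "version": {"type": "string"}
      },
      "additionalProperties": false
    },
    "fixedCriterion": {
      "type": "object",
      "required": ["searchParameter", "fhirPath", "values"],
      "additionalProperties": false,
      "properties": {
        "searchParameter": {"type": "string", "minLength": 1},
        "fhirPath": {"type": "string", "minLength": 1},
        "values": {
          "type": "array",
          "items": {"$ref": "#/$defs/termCode"},
          "minItems": 1
        }
      }
    },
    "entry": {
      "type": "object",
      "required": [
        "key", "resourceType", "termCodeSearchParameter",
        "termCodeFhirPath", "valueKind", "fixedCriteria"
      ],
      "additionalProperties": false,
      "properties": {
        "key": {"$ref": "#/$defs/termCode"},
        "resourceType": {"type": "string", "minLength": 1},
        "termCodeSearchParameter": {"type": "string", "minLength": 1},
        "termCodeFhirPath": {"type": "string", "minLength": 1},
        "valueSearchParameter": {"type": ["string", "null"]},
        "valueFhirPath": {"type": ["string", "null"]},
        "valueKind": {
          "enum": [
            "none", "concept", "quantity", "component-concept",
            "component-quantity", "integer-score", "conclusion-text"
          ]
        },
        "fixedCriteria": {
          "type": "array",
          "items": {"$ref": "#/$defs/fixedCriterion"}
        }
      }
    }
  }
}
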