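{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "UI profiles: array of category trees",
  "type": "array",
  "items": {
    "type": "object",
    "required": ["categoryName", "roots"],
    "additionalProperties": false,
    "properties": {
      "categoryName": {"type": "string", "minLength": 1},
      "roots": {"type": "array", "items": {"$ref": "#/$defs/node"}}
    }
  },
  "$defs": {
    "termCode": {
      "type": "object",
      "required": ["system", "code", "display"],
      "properties": {
        "system": {"type": "string", "minLength": 1},
        "code": {"type": "string", "minLength": 1},
        "display": {"type": "string"},
        "version": {"type": "string"}
      },
      "additionalProperties": false
    },
    "valueDefinition": {
      "type": "object",
      "required": ["kind"],
      "properties": {
        "kind": {"enum": ["concept", "quantity"]},
        "selectableConcepts": {
          "type": "array",
          "items": {"$ref": "#/$defs/termCode"},
          "minItems": 1
        },
        "allowedUnits": {
          "type": "array",
          "items": {"type": "string"},
          "minItems": 1
        },
        "comparators": {
          "type": "array",
          "items": {"enum": ["eq", "ne", "le", "ge", "lt", "gt"]}
        }
      },
      "additionalProperties": false
    },
    "node": {
      "type": "object",
      "required": ["termCode", "display", "selectable", "children", "valueDefinition"],
      "additionalProperties": false,
      "properties": {
        "termCode": {"$ref": "#/$defs/termCode"},
        "display": {"type": "string"},
        "selectable": {"type": "boolean"},
        "children": {"type": "array", "items": {"$ref": "#/$defs/node"}},
        "valueDefinition": {
          "oneOf": [{"type": "null"}, {"$ref": "#/$defs/valueDefinition"}]
        }
      }
    }
  }
}
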