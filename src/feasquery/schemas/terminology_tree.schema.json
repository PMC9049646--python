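{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Terminology tree: codes and child lists only",
  "type": "object",
  "required": ["roots"],
  "additionalProperties": false,
  "properties": {
    "roots": {"type": "array", "items": {"$ref": "#/$defs/node"}}
  },
  "$defs": {
    "node": {
      "type": "object",
      "required": ["termCode", "children"],
      "additionalProperties": false,
      "properties": {
        "termCode": {
          "type": "object",
          "required": ["system", "code"],
          "additionalProperties": false,
          "properties": {
            "system": {"type": "string", "minLength": 1},
            "code": {"type": "string", "minLength": 1}
          }
        },
        "children": {"type": "array", "items": {"$ref": "#/$defs/node"}}
      }
    }
  }
}
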