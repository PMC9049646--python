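{
  "$defs": {
    "ConceptFilter": {
      "additionalProperties": false,
      "properties": {
        "kind": {
          "const": "concept",
          "default": "concept",
          "title": "Kind",
          "type": "string"
        },
        "selectedConcepts": {
          "items": {
            "$ref": "#/$defs/WireTermCode"
          },
          "minItems": 1,
          "title": "Selectedconcepts",
          "type": "array"
        }
      },
      "required": [
        "selectedConcepts"
      ],
      "title": "ConceptFilter",
      "type": "object"
    },
    "CriterionClause": {
      "additionalProperties": false,
      "description": "One criterion: alternative codes for the same concept, plus an\noptional value restriction.",
      "properties": {
        "termCodes": {
          "items": {
            "$ref": "#/$defs/WireTermCode"
          },
          "minItems": 1,
          "title": "Termcodes",
          "type": "array"
        },
        "valueFilter": {
          "anyOf": [
            {
              "discriminator": {
                "mapping": {
                  "concept": "#/$defs/ConceptFilter",
                  "quantity-comparator": "#/$defs/QuantityComparatorFilter",
                  "quantity-range": "#/$defs/QuantityRangeFilter"
                },
                "propertyName": "kind"
              },
              "oneOf": [
                {
                  "$ref": "#/$defs/ConceptFilter"
                },
                {
                  "$ref": "#/$defs/QuantityComparatorFilter"
                },
                {
                  "$ref": "#/$defs/QuantityRangeFilter"
                }
              ]
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Valuefilter"
        }
      },
      "required": [
        "termCodes"
      ],
      "title": "CriterionClause",
      "type": "object"
    },
    "QuantityComparatorFilter": {
      "additionalProperties": false,
      "properties": {
        "kind": {
          "const": "quantity-comparator",
          "default": "quantity-comparator",
          "title": "Kind",
          "type": "string"
        },
        "comparator": {
          "enum": [
            "eq",
            "ne",
            "le",
            "ge",
            "lt",
            "gt"
          ],
          "title": "Comparator",
          "type": "string"
        },
        "value": {
          "title": "Value",
          "type": "number"
        },
        "unit": {
          "minLength": 1,
          "title": "Unit",
          "type": "string"
        }
      },
      "required": [
        "comparator",
        "value",
        "unit"
      ],
      "title": "QuantityComparatorFilter",
      "type": "object"
    },
    "QuantityRangeFilter": {
      "additionalProperties": false,
      "properties": {
        "kind": {
          "const": "quantity-range",
          "default": "quantity-range",
          "title": "Kind",
          "type": "string"
        },
        "minValue": {
          "title": "Minvalue",
          "type": "number"
        },
        "maxValue": {
          "title": "Maxvalue",
          "type": "number"
        },
        "unit": {
          "minLength": 1,
          "title": "Unit",
          "type": "string"
        }
      },
      "required": [
        "minValue",
        "maxValue",
        "unit"
      ],
      "title": "QuantityRangeFilter",
      "type": "object"
    },
    "WireTermCode": {
      "additionalProperties": false,
      "properties": {
        "system": {
          "minLength": 1,
          "title": "System",
          "type": "string"
        },
        "code": {
          "minLength": 1,
          "title": "Code",
          "type": "string"
        },
        "display": {
          "default": "",
          "title": "Display",
          "type": "string"
        },
        "version": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Version"
        }
      },
      "required": [
        "system",
        "code"
      ],
      "title": "WireTermCode",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "properties": {
    "version": {
      "const": "feasquery-sq-1",
      "default": "feasquery-sq-1",
      "title": "Version",
      "type": "string"
    },
    "inclusion": {
      "items": {
        "items": {
          "$ref": "#/$defs/CriterionClause"
        },
        "type": "array"
      },
      "title": "Inclusion",
      "type": "array"
    },
    "exclusion": {
      "items": {
        "items": {
          "$ref": "#/$defs/CriterionClause"
        },
        "type": "array"
      },
      "title": "Exclusion",
      "type": "array"
    }
  },
  "required": [
    "inclusion"
  ],
  "title": "Structured Query (feasquery-sq-1)",
  "type": "object",
  "$schema": "https://json-schema.org/draft/2020-12/schema"
}
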