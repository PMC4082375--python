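{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "historygraph/graph-v1",
  "title": "History graph interchange document",
  "type": "object",
  "required": ["vertices"],
  "properties": {
    "format": {"const": "historygraph/v1"},
    "vertices": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "label": {"type": ["string", "null"], "pattern": "^[ACGT]+$"}
        }
      }
    },
    "adjacencies": {
      "type": "array",
      "items": {
        "type": "array",
        "minItems": 2,
        "maxItems": 2,
        "items": {
          "type": "array",
          "prefixItems": [
            {"type": "string"},
            {"enum": ["head", "tail"]}
          ]
        }
      }
    },
    "branches": {
      "type": "array",
      "items": {
        "type": "array",
        "minItems": 2,
        "maxItems": 2,
        "items": {"type": "string"}
      }
    },
    "provenance": {"type": "object"}
  }
}
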