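{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "smilight molecule records",
  "description": "Input document for smilight render: molecules with attribution scores. A bare array of molecule objects is accepted as shorthand for {schema_version, molecules}.",
  "type": "object",
  "required": ["molecules"],
  "properties": {
    "schema_version": {"const": 1},
    "molecules": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["smiles", "scores"],
        "properties": {
          "id": {
            "type": "string",
            "description": "Optional; defaults to the record index."
          },
          "smiles": {"type": "string", "minLength": 1},
          "scores": {
            "type": "array",
            "items": {"type": "number"},
            "description": "Length must equal either the atom count or the token count of the SMILES as written."
          },
          "attributes": {
            "type": "object",
            "additionalProperties": {"type": "string"},
            "description": "Ordered key/value rows shown under the bar chart."
          },
          "config": {
            "type": "object",
            "description": "Partial visual-config override for this record (palette, domain, thresholds, show_score_labels, black_atoms, geometry).",
            "properties": {
              "palette": {
                "oneOf": [
                  {"type": "string"},
                  {"type": "array", "items": {"type": "string"}}
                ]
              },
              "domain": {
                "type": "array",
                "items": {"type": "number"},
                "minItems": 2,
                "maxItems": 3
              },
              "thresholds": {
                "type": "array",
                "items": {"type": "number", "minimum": 0, "maximum": 1}
              },
              "show_score_labels": {"type": "boolean"},
              "black_atoms": {"type": "boolean"}
            }
          }
        },
        "additionalProperties": true
      }
    }
  }
}
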