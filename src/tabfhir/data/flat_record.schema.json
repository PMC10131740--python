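{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Flat harmonized record",
  "description": "One flattened observation from a FHIR resource: exactly the four keys feature_name, table_name, value and metadata.",
  "type": "object",
  "properties": {
    "feature_name": {"type": "string", "minLength": 1},
    "table_name": {"type": "string", "pattern": "^[a-z][a-z]*$"},
    "value": {"type": ["string", "number", "boolean", "null"]},
    "metadata": {
      "type": "object",
      "additionalProperties": {"type": ["string", "number", "boolean"]}
    }
  },
  "required": ["feature_name", "table_name", "value", "metadata"],
  "additionalProperties": false
}
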