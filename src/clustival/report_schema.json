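{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "clustival metric report",
  "type": "object",
  "required": ["package", "version", "config", "results"],
  "properties": {
    "package": {"const": "clustival"},
    "version": {"type": "string"},
    "seed": {"type": ["integer", "null"]},
    "config": {"type": "object"},
    "results": {
      "type": "object",
      "additionalProperties": {
        "type": ["number", "null", "object", "array"]
      }
    }
  },
  "additionalProperties": false
}
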