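{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "etepm analysis report",
  "type": "object",
  "required": ["config", "definitions", "linearity_gate", "seed"],
  "properties": {
    "seed": {"type": "integer"},
    "config": {"type": "object"},
    "assembly": {
      "type": "object",
      "properties": {
        "n_subjects": {"type": "integer"},
        "n_kept": {"type": "integer"}
      }
    },
    "linearity_gate": {
      "type": "object",
      "required": ["choice", "p"],
      "properties": {
        "choice": {"type": "string", "enum": ["linear-dlm", "ncs-dlnm"]},
        "p": {"type": "number"},
        "chi2": {"type": "number"},
        "df": {"type": "integer"}
      }
    },
    "definitions": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["effects"],
        "properties": {
          "effects": {"type": "object"},
          "interaction": {"type": "object"},
          "attributable": {"type": "object"},
          "thresholds": {"type": "object"}
        }
      }
    },
    "subgroups": {"type": "object"},
    "sensitivity": {"type": "object"}
  }
}
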