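{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "PRS-PheWAS results payload",
  "type": "object",
  "required": ["metadata", "n_studies", "alpha", "significance_threshold", "results"],
  "properties": {
    "metadata": {"type": "object"},
    "n_studies": {"type": "integer", "minimum": 1},
    "alpha": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
    "significance_threshold": {"type": "number", "exclusiveMinimum": 0},
    "results": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["phecode", "group", "neglog10_p", "direction", "or",
                     "ci_lower", "ci_upper", "n_case", "n_control",
                     "significant", "invalid"],
        "properties": {
          "phecode": {"type": "string"},
          "description": {"type": "string"},
          "group": {"type": "string"},
          "neglog10_p": {"type": ["number", "null"]},
          "direction": {"enum": ["up", "down"]},
          "or": {"type": "number"},
          "ci_lower": {"type": "number"},
          "ci_upper": {"type": "number"},
          "beta": {"type": "number"},
          "se": {"type": "number"},
          "p": {"type": ["number", "null"]},
          "n_case": {"type": "integer"},
          "n_control": {"type": "integer"},
          "significant": {"type": "boolean"},
          "invalid": {"type": "boolean"}
        }
      }
    }
  }
}
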