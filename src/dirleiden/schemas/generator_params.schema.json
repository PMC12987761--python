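{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Synthetic benchmark generator parameters",
  "type": "object",
  "required": ["n", "mu", "avg_degree", "max_degree", "tau1", "tau2",
               "min_comm", "max_comm", "directed", "seed"],
  "properties": {
    "n": {"type": "integer", "minimum": 1},
    "mu": {"type": "number", "minimum": 0, "maximum": 1},
    "avg_degree": {"type": "number", "minimum": 1},
    "max_degree": {"type": "integer", "minimum": 1},
    "tau1": {"type": "number"},
    "tau2": {"type": "number"},
    "min_comm": {"type": "integer", "minimum": 1},
    "max_comm": {"type": "integer", "minimum": 1},
    "directed": {"type": "boolean"},
    "seed": {"type": "integer"},
    "realized_mu": {"type": "number", "minimum": 0, "maximum": 1}
  }
}
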