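{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Multi-seed stability report",
  "type": "object",
  "required": ["n_runs", "seeds", "mean_pairwise_nmi", "q_values",
               "runtime_cv_pct"],
  "properties": {
    "n_runs": {"type": "integer", "minimum": 2},
    "seeds": {"type": "array", "items": {"type": "integer"}},
    "mean_pairwise_nmi": {"type": "number", "minimum": 0, "maximum": 1},
    "q_values": {"type": "array", "items": {"type": "number"}},
    "runtime_cv_pct": {"type": "number", "minimum": 0}
  }
}
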