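{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Clustering run report",
  "type": "object",
  "required": ["n", "m", "directed", "gamma", "seed", "passes", "q_trace",
               "moved_per_pass", "n_communities", "final_q"],
  "properties": {
    "n": {"type": "integer", "minimum": 0},
    "m": {"type": "number", "minimum": 0},
    "directed": {"type": "boolean"},
    "gamma": {"type": "number", "minimum": 0},
    "seed": {"type": "integer"},
    "passes": {"type": "integer", "minimum": 1},
    "q_trace": {"type": "array", "items": {"type": "number"}},
    "moved_per_pass": {"type": "array", "items": {"type": "integer"}},
    "n_communities": {"type": "integer", "minimum": 0},
    "final_q": {"type": "number"}
  }
}
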