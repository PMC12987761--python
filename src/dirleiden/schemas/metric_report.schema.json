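{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Partition-similarity metric report",
  "type": "object",
  "required": ["nmi", "rand", "structural_rand", "agreement_pct",
               "n_communities_a", "n_communities_b", "inter_weight_delta"],
  "properties": {
    "nmi": {"type": "number", "minimum": 0, "maximum": 1},
    "rand": {"type": "number", "minimum": 0, "maximum": 1},
    "structural_rand": {"type": "number"},
    "agreement_pct": {"type": "number", "minimum": 0, "maximum": 100},
    "n_communities_a": {"type": "integer", "minimum": 0},
    "n_communities_b": {"type": "integer", "minimum": 0},
    "inter_weight_delta": {"type": "number"}
  }
}
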