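{
  "type": "object",
  "required": ["schema_version", "seed", "parameters", "n_frames", "n_beads",
               "clusters", "contacts", "diffusion", "sasa", "domains"],
  "properties": {
    "schema_version": {"type": "integer"},
    "seed": {"type": "integer"},
    "parameters": {"type": "object"},
    "n_frames": {"type": "integer"},
    "n_beads": {"type": "integer"},
    "clusters": {
      "type": "object",
      "required": ["n_clusters", "final_count", "aggregation_time_ns"],
      "properties": {
        "n_clusters": {"type": "array", "items": {"type": "integer"}},
        "final_count": {"type": "integer"},
        "aggregation_time_ns": {"type": ["number", "string"]}
      }
    },
    "contacts": {
      "type": "object",
      "required": ["n_frames", "total_per_frame", "max_P", "n_high_P_pairs"],
      "properties": {
        "n_frames": {"type": "integer"},
        "total_per_frame": {"type": "number"},
        "max_P": {"type": "number"},
        "n_high_P_pairs": {"type": "integer"}
      }
    },
    "diffusion": {
      "type": "object",
      "required": ["early", "late"],
      "properties": {
        "early": {"type": "object", "required": ["D_1e-8_cm2_s", "stderr"]},
        "late": {"type": "object", "required": ["D_1e-8_cm2_s", "stderr"]}
      }
    },
    "sasa": {
      "type": "object",
      "required": ["n_buried", "buried_residues", "mean_delta"],
      "properties": {
        "n_buried": {"type": "integer"},
        "buried_residues": {"type": "array", "items": {"type": "integer"}},
        "mean_delta": {"type": "number"}
      }
    },
    "domains": {
      "type": ["object", "null"],
      "required": [],
      "properties": {
        "ratio_dppc_dlipc": {"type": "number"},
        "stderr": {"type": "number"},
        "mean_counts": {"type": "object"},
        "demix_ratio_first": {"type": "number"},
        "demix_ratio_last": {"type": "number"}
      }
    }
  }
}
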