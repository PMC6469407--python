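{
  "n_regions": 1,
  "total_bp": 975000,
  "genome_bp": 2000000,
  "pct_genome": 48.75,
  "class_counts": {
    "fixed_high": 1
  },
  "fst_threshold": 0.9928057553956835,
  "param_hash": "e92b2a452199"
}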