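{
  "n_species": 5,
  "tips_per_species": 8,
  "birth_rate": 1.0,
  "theta": 0.005,
  "seq_length": 500,
  "mu": 0.05,
  "seed": 2026,
  "min_species_depth": 0.6
}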