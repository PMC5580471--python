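{
  "_comment": "Synthetic host-regime codon-preference presets for the data generator. These are stand-ins with explicit weights, not estimates from real genomes: each sense codon's sampling weight is the weight of its third base. Insect-like sequences prefer A/T-ending codons, plant-like sequences prefer G/C-ending codons.",
  "insect_like": {
    "third_base_weight": {"A": 4.0, "T": 4.0, "C": 1.0, "G": 1.0}
  },
  "plant_like": {
    "third_base_weight": {"A": 1.0, "T": 1.0, "C": 4.0, "G": 4.0}
  },
  "uniform": {
    "third_base_weight": {"A": 1.0, "T": 1.0, "C": 1.0, "G": 1.0}
  }
}
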