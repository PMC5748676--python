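{
  "ancestor_length": 98,
  "anchor_length": 200,
  "anchor_name": "anchor",
  "between_group_sub_rate": 0.15,
  "box_mutation_rate": 0.01,
  "chrom": "chrSim",
  "group_sizes": [
    9,
    15,
    6
  ],
  "indel_length_geometric_p": 0.5,
  "indel_rate": 0.002,
  "intergenic_spacer_bp": [
    800,
    2000
  ],
  "label": "human_like",
  "n_outliers": 0,
  "outlier_sub_rate": 0.35,
  "rng_seed": 42,
  "strand": "+",
  "within_group_sub_rate": 0.02
}
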