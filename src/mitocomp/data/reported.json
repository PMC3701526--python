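{
  "comment": "Published survey values for the two rice-planthopper mitogenomes (BPH = Nilaparvata lugens, SBPH = Laodelphax striatellus). These are inputs to desk-scale analyses and to the default synthetic-genome specifications.",
  "base_counts_j_strand": {
    "bph": {"a": 7393, "t": 6165, "g": 1661, "c": 2400},
    "sbph": {"a": 7099, "t": 5581, "g": 1527, "c": 2224}
  },
  "repeat_units": {
    "bph": "GGAAAAAATGTCACGTTTTTC",
    "sbph": "CACGATTTTTGGAAAAAATGT"
  },
  "repeat_copy_numbers": {"bph": 55, "sbph": 35},
  "poly_t_length_bp": 23,
  "gene_divergence_rates": {"rrnS": 0.008, "rrnL": 0.0016},
  "rrna_lengths_bp": {"rrnS": 747, "rrnL": 1219},
  "trnh_fragment_segments_bp": {"nad5": 482, "trnH": 62, "intergenic": 2, "nad4": 96},
  "sample_size": 309,
  "major_haplotype_counts": [178, 93, 18],
  "nonsynonymous_sites": {"277": "M93L", "391": "D131N"},
  "sbph_vs_prior_indel_lengths_bp": [57, 21, 84, 55, 21, 60]
}
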