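{
  "seed": 17,
  "simulation": {
    "genome_length": 1000000,
    "n_genes": 200,
    "gene_length": 900,
    "het_snv_rate": 3.8,
    "het_indel_rate": 0.6,
    "divergence_snv_rate": 6.9,
    "divergence_indel_rate": 0.8,
    "insert_tiers": [[300, 30, 20.0], [3000, 300, 8.0], [8000, 800, 5.0]],
    "mite_insertion_prob": 0.3,
    "mite_shared_prob": 0.2,
    "suppression_log2fc": -2.0,
    "nb_dispersion": 0.05,
    "n_replicates": 5
  }
}
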