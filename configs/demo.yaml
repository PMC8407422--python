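# Demo study: two-condition synthetic genome with deep 5'-end libraries.
outdir: demo_out
seed: 42
simulate:
  genome_length: 150000
  n_genes: 100
  library_depth: 1500000
  dispersion: 0.1
  frame0_fraction: 0.8
  tss_enrichment: 8.0
  utr_median_nt: 49
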