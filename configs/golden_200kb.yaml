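# Golden end-to-end fixture: 2 x 100 kb synthetic genome, all stages.
outdir: defensescan_out
seed: 42
simulate:
  n_chrom: 2
  chrom_length: 100000
  n_genes: 10
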