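# demo pipeline configuration (small, runs in seconds)
seed: 7
simulation:
  n_genes: 25
  depth_per_library: 60000
  n_de_genes: 5
  expression_noise_sd: 0.2
  ct_noise_sd: 0.1
peak_calling:
  fdr: 0.05
  min_fold: 2
de:
  alpha: 0.05
  fold: 1.5
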