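# Demo configuration for `budsig run` on a down-scaled synthetic cohort.
# Analysis thresholds keep their standard defaults; only problem sizes and the
# permutation count are reduced so the demo completes in seconds.
outdir: demo_output
seed: 1
spatial:
  n_genes: 150
  segments_per_type: 1
diffcorr:
  n_perm: 500
  max_genes: 40
evaluate:
  n_samples: 120
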