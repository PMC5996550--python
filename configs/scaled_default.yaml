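# Scaled study configuration: 300-gene genome, 120-tumor cohort,
# 3 networks x 10 permutations (the full 10 x 25 setup is the library
# default; it is available by overriding inference.n_networks and
# validation.n_random).
seed: 1
outdir: results/cohort_run
inference:
  n_networks: 3
validation:
  n_random: 10
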