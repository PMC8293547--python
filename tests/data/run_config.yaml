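# Reference study configuration used by the reproducibility check:
# a compact simulated study small enough to run twice in seconds.
scenario:
  n_regions: 36
  lattice_dims: [6, 6]
  households_per_region: 150
  seed: 7
n_perm: 199
spatial_seed: 7
cv_seed: 7
k_folds: 5
n_lambda: 40
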