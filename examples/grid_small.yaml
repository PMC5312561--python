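# A small simulation grid: 2 size layouts x 2 heterogeneity levels x 1
# correlation x 1 generation mode = 4 scenarios.  Mirrors the structure of
# the full experimental grid; expand the lists to enlarge it.
sizes:
  - {n_studies: 15, total_size: 500, size_scheme: imbalanced}
  - {n_studies: 15, total_size: 3000, size_scheme: imbalanced}
tau0_sq: [1, 4]
tau1_sq: [1, 4]
rho: [0.5]
generation_mode: [random_intercept]
beta0: -0.85
beta1: 0.18
n_reps: 1000
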