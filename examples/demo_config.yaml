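# Demo configuration for `paslab run`: full synthetic workflow
# (simulate -> pas -> screen -> pharm) with planted effects.
seed: 7
alpha: 0.05
r_min: 0.2
log_base: 10.0
pal_threshold: 0.3
activated: ERK_survival
pathway:
  delta: 1.0
  sigma: 0.2
  n_case: 3
  n_ctrl: 3
signatures:
  rho: 0.7
  n_samples: 100
  n_genes_per_sig: 5
  n_sigs: 4
pharm:
  n_lines: 60
  slope: 1.0
  noise_ratio: 0.5
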