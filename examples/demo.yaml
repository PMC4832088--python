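# Scaled-down demo profile for `vbmpattern run-all`.
# Full-scale study defaults (z 4.25, 10,000 CV iterations, 20% subset
# fraction, 100,000 importance iterations, 1,000 permutations) apply
# when a block is omitted; this profile trims the iteration counts so a
# complete run finishes in well under five minutes on one core.
seed: 7

cohort:
  grid_shape: [32, 32, 32]
  n_cases: 22
  n_controls: 27
  smoothing_fwhm_mm: 4.0
  # omit `clusters` to plant the default layout: two case>control
  # spheres and one control>case sphere at strong amplitude

selection:
  z_threshold: 4.25
  two_sided: true
  scope: split

cv:
  n_iterations: 500

permutation:
  n_permutations: 50
  iterations_per_perm: 40

importance:
  n_iterations: 1500
  subset_fraction: 0.20
  min_selected: 50

clusters:
  percentile: 50
  connectivity: 26
  min_size: 10
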