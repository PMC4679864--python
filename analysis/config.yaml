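# Shared configuration for the numbered analysis scripts: one 8-subject
# cohort, two disruption conditions, planted category and relevance codes at
# the calibrated (~70% single-subject decoding) amplitudes, desk-scale
# inference counts.
sim:
  n_subjects: 8
  grid_dims: [12, 12, 8]
  seed: 20260926
n_perm: 500
n_null: 20
n_boot: 5000
seed: 20260926
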