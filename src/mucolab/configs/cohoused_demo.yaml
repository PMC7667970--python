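# Co-housed lean vs ob/ob demo cohort.
# Co-housing exchanges microbiota through coprophagy; mucus parameters of
# both genotypes fully converge to the shared intermediate values
# (convergence: 1.0), so the penetrability and growth-rate contrasts are
# null, while the metabolic covariates remain genotype-specific.
seed: 0
bin_width_um: 5.0
cohort:
  housing: cohoused
  convergence: 1.0
  n_stacks_per_mouse: 3
  beads_per_stack: 300
  distance_noise_um: 2.0
  thickness_noise_um: 10.0
  groups:
    - label: lean
      n: 8
      body_weight_g: [30.0, 3.0]
      fasting_glucose_mM: [8.0, 1.5]
      fasting_insulin_uU_ml: [10.0, 3.0]
      growth_rate_um_min: [2.0, 0.3]
      initial_thickness_um: [400.0, 40.0]
      mucus:
        thickness_um: 80.0
        penetration_fraction: 0.1
        surface_jitter_um: 2.0
    - label: obob
      n: 8
      body_weight_g: [55.0, 5.0]
      fasting_glucose_mM: [10.0, 2.0]
      fasting_insulin_uU_ml: [60.0, 15.0]
      growth_rate_um_min: [1.0, 0.3]
      initial_thickness_um: [400.0, 40.0]
      mucus:
        thickness_um: 80.0
        penetration_fraction: 0.6
        surface_jitter_um: 2.0
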