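simulate:
  n_individuals: 5000
  seed: 7
  amplitude_true: 0.092      # outcome SD units
  acrophase_true: -0.14      # radians, peak just before New Year
  noise_sd: 1.0
  covariates:
    - {name: age, dist: normal, mean: 56.92, sd: 8.0, effect: -0.005}
    - {name: bmi, dist: normal, mean: 27.41, sd: 4.69}
    - {name: female, dist: binary, prevalence: 0.54, effect: 0.043}
  markers:
    - {name: m1, dist: binary, prevalence: 0.456,
       displacement: -0.1, amplitude_change: -0.02}
    - {name: m2, dist: linear, mean: 0.0, sd: 1.0, acrophase_shift: 0.05}
  diseases:
    - {name: cardiovascular, incidence: 0.1, amplitude_ratio: 0.835}
  death: {rate: 0.05, amplitude_ratio: 0.772, followup_range: [0.01, 15.5]}
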