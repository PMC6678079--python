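# Compact two-random-coefficient model: constant + age/sex dummies per
# equation; random SDs on rear age and front sex.
outcomes:
  rear: injury__rear
  front: injury__front
  n_categories: 4
equations:
  rear:
    constant: {random: false}
    covariates:
      - {name: age_le24, random: true}
      - sex_male
  front:
    constant: {random: false}
    covariates:
      - age_le24
      - {name: sex_male, random: true}
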