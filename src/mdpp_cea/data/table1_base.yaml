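model:
  starting_age: 55
  horizon_cycles: 36
  annual_discount_rate: 0.03
  psa_iterations: 1000
  rng_seed: 12345
  scenario:
    mets_resolution_mode: base
    equalize_rfpos_utilities: false
    parameter_overrides: {}
parameters:
  units: proportion
  starting_age:
    family: uniform
    base: 55
    low: 45
    high: 65
  fraction_female:
    family: beta
    base: 0.75
    low: 0.482
    high: 0.94
  fraction_african_american:
    family: beta
    base: 0.271
    low: 0.065
    high: 0.558
  prev_angina:
    family: beta
    base: 0.038
    low: 0.01
    high: 0.083
  prev_htn_treated:
    family: beta
    base: 0.849
    low: 0.045
    high: 1.0
  prev_mi:
    family: beta
    base: 0.019
    low: 0.005
    high: 0.042
  prev_stroke:
    family: beta
    base: 0.019
    low: 0.005
    high: 0.042
  prev_pvd:
    family: beta
    base: 0.047
    low: 0.013
    high: 0.102
  p_screen_positive:
    family: beta
    base: 0.31
    low: 0.072
    high: 0.635
  p_enroll:
    family: beta
    base: 0.47
    low: 0.092
    high: 0.867
  p_dm_rfpos_no_program_yr:
    family: beta
    base: 0.108
    low: 0.029
    high: 0.233
  p_dm_rfneg_yr:
    family: beta
    base: 0.004
    low: 0.0005
    high: 0.0075
  p_dm_in_program_yr:
    family: beta
    base: 0.048
    low: 0.013
    high: 0.105
  p_become_rfpos_yr:
    family: beta
    base: 0.04
    low: 0.01
    high: 0.087
  p_progress_complicated_yr:
    family: beta
    base: 0.075
    low: 0.02
    high: 0.163
  p_resolve_no_program_yr:
    family: beta
    base: 0.121
    low: 0.032
    high: 0.259
  p_resolve_in_program_yr:
    family: beta
    base: 0.162
    low: 0.042
    high: 0.344
  rr_death_rfpos:
    family: log-normal
    base: 1.7
    low: 1.5
    high: 1.8
  rr_death_rfneg:
    family: fixed
    base: 1.0
  rr_death_stable_dm:
    family: log-normal
    base: 2.0
    low: 1.8
    high: 2.2
  rr_death_complicated_dm:
    family: log-normal
    base: 2.4
    low: 2.2
    high: 2.6
  u_rfpos_usual:
    family: uniform
    base: 0.73
    low: 0.71
    high: 0.75
  u_rfpos_program:
    family: uniform
    base: 0.75
    low: 0.73
    high: 0.77
  u_rfneg:
    family: uniform
    base: 0.88
    low: 0.84
    high: 0.92
  u_stable_dm:
    family: uniform
    base: 0.69
    low: 0.66
    high: 0.72
  u_complicated_dm:
    family: uniform
    base: 0.59
    low: 0.51
    high: 0.68
  c_screen_positive:
    family: uniform
    base: 35
    low: 18
    high: 53
  c_screen_negative:
    family: uniform
    base: 32
    low: 16
    high: 48
  c_program:
    family: uniform
    base: 219
    low: 110
    high: 329
  c_rfpos_yr:
    family: fixed
    base: 1296
  c_rfneg_yr:
    family: fixed
    base: 616
  c_dm_base_yr:
    family: fixed
    base: 1684
  c_complicated_dm_base_yr:
    family: fixed
    base: 1684
  mult_rfpos_female:
    family: normal
    base: 1.14
    low: 1.05
    high: 1.25
  mult_rfpos_aa:
    family: normal
    base: 0.82
    low: 0.7
    high: 0.95
  mult_dm_female:
    family: normal
    base: 1.25
    low: 1.14
    high: 1.35
  mult_dm_aa:
    family: normal
    base: 0.82
    low: 0.7
    high: 0.95
  mult_comp_female:
    family: normal
    base: 1.25
    low: 1.14
    high: 1.35
  mult_comp_aa:
    family: normal
    base: 0.82
    low: 0.7
    high: 0.95
  mult_comp_angina:
    family: normal
    base: 1.73
    low: 1.31
    high: 2.14
  mult_comp_htn:
    family: normal
    base: 1.24
    low: 1.1
    high: 1.37
  mult_comp_mi:
    family: normal
    base: 1.9
    low: 1.64
    high: 2.17
  mult_comp_stroke:
    family: normal
    base: 1.3
    low: 1.2
    high: 1.4
  mult_comp_pvd:
    family: normal
    base: 1.31
    low: 1.1
    high: 1.53
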