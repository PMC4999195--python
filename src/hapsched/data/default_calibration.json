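{
  "control_death": 0.01,
  "control_net_base": 0.018,
  "control_net_span": 0.01,
  "control_net_k_o": 2.0,
  "sens_imax_base": 0.7,
  "sens_imax_span": 0.25,
  "sens_imax_k_o": 1.0,
  "sens_ec50_base": 0.06,
  "sens_ec50_tolerance": 0.5,
  "sens_ec50_k_o": 0.5,
  "sens_death_span": 0.0,
  "hill_erlotinib": 2.0,
  "res_imax_top": 0.5,
  "res_ec50": 1.0,
  "res_hill": 2.0,
  "viab_a_max": 6.0,
  "viab_k_o": 0.4,
  "viab_k_c2": 4.0,
  "mutation_rate": 1e-07,
  "literal_eq9": false
}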