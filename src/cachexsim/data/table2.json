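{
  "tumor_params": {"mu": 0.446, "mu1": 116.0, "eta": 20.0, "T0_mm3": 0.5, "rmse_context": 34.11},
  "cachexia_params": {"eps": 0.004, "dS": 0.030, "dM": 0.104, "m2": 338.0, "rmse_context": 0.157},
  "group_a_initial_conditions": {"M_mm3": 4799.25, "S_mm3": 252.75, "day0_weight_g": 25.26},
  "group_b_initial_conditions": {"M_mm3": 4768.85, "S_mm3": 251.15, "day0_weight_g": 25.10},
  "treatment_group_a": {"A1": 0.0, "A2": 0.0, "A3": 0.51, "A4": 0.54, "t_start": 5.0, "rmse_context": 0.176},
  "treatment_group_b": {"A1": 0.0, "A2": 0.0, "A3": 0.62, "A4": 1.0, "t_start": 14.0, "rmse_context": 0.317}
}
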