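{
  "healthy_params": {
    "p0": 0.479,
    "p1": 0.133,
    "nu0": 0.087,
    "nu1": 5.591,
    "d0": 0.05,
    "m": 1000.0
  },
  "printed_initial_conditions": {
    "comment": "Printed alongside the healthy parameters as 'initial conditions estimated for a 3-week-old mouse'. Numerically these are the day-49 state of the growth solve started from the lean-deconstruction of the 11.26 g three-week weight (their ratio equals the day-49 stem ratio), so the package treats them as the 10-week reference state.",
    "S_g": 0.536,
    "M_g": 10.17784,
    "S_mm3": 268.01,
    "M_mm3": 5088.92,
    "xi_g_per_mm3": 0.002
  },
  "rmse_context": 0.168
}
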