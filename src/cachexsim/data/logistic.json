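{
  "logistic_params": {"alpha": 0.0756, "K": 28.3, "W0": 11.26},
  "schedule": {
    "observed_days": "weekly 0-84",
    "extension": "every 10 days from day 90 to day 300"
  }
}
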