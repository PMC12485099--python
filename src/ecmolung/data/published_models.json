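{
  "imaging": {
    "intercept": 1.854,
    "coefficients": {"normal_vent": -6.195},
    "cutoff": 0.247
  },
  "clinical": {
    "intercept": 1.594,
    "coefficients": {"age": -0.095, "pmean": 0.087, "lactate": 0.559, "crp": 0.005},
    "cutoff": 0.225
  },
  "combined": {
    "intercept": 3.775,
    "coefficients": {"age": -0.086, "pmean": 0.065, "lactate": 0.481, "crp": 0.004, "normal_vent": -4.396},
    "cutoff": 0.304
  }
}
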