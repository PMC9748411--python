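{
  "prediction_scl_r50": {
    "description": "Best-fit prediction-group equation (2/3 of the sample), SCL^2/R50 index",
    "length_basis": "scl",
    "resistance_basis": "r50",
    "intercept": -0.06,
    "index": -0.32,
    "body_mass": 1.09,
    "time": -0.14,
    "n_fit": 33
  },
  "prediction_ccl_r50": {
    "description": "Best-fit prediction-group equation (2/3 of the sample), CCL^2/R50 index",
    "length_basis": "ccl",
    "resistance_basis": "r50",
    "intercept": -0.04,
    "index": -0.30,
    "body_mass": 1.09,
    "time": -0.14,
    "n_fit": 33
  },
  "final_scl_r50": {
    "description": "Final recommended equation (full sample), SCL^2/R50 index",
    "length_basis": "scl",
    "resistance_basis": "r50",
    "intercept": -0.03,
    "index": -0.29,
    "body_mass": 1.07,
    "time": -0.11,
    "n_fit": 49
  },
  "final_ccl_r50": {
    "description": "Final recommended equation (full sample), CCL^2/R50 index",
    "length_basis": "ccl",
    "resistance_basis": "r50",
    "intercept": -0.01,
    "index": -0.28,
    "body_mass": 1.07,
    "time": -0.10,
    "n_fit": 49
  }
}
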