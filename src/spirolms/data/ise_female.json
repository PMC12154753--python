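{
  "schema_version": 1,
  "name": "ISE-female",
  "sex": "female",
  "valid_age_range": [18.0, 70.0],
  "acknowledge_missing_splines": true,
  "indices": {
    "fev1": {
      "family": "BCCG",
      "mu": {"link": "identity", "intercept": -24.46931, "beta_log_height": 5.85935, "beta_log_age": -0.65217, "spline": null, "spline_declared": true},
      "sigma": {"link": "log", "intercept": -2.8156, "beta_log_height": 0.0, "beta_log_age": 0.1647, "spline": null, "spline_declared": true},
      "nu": {"link": "identity", "intercept": -2.293, "beta_log_height": 0.0, "beta_log_age": 0.2341, "spline": null, "spline_declared": false}
    },
    "fvc": {
      "family": "BCCG",
      "mu": {"link": "log", "intercept": -11.26749, "beta_log_height": 2.61061, "beta_log_age": -0.22545, "spline": null, "spline_declared": false},
      "sigma": {"link": "log", "intercept": -2.0873, "beta_log_height": 0.0, "beta_log_age": 0.0, "spline": null, "spline_declared": false},
      "nu": {"link": "identity", "intercept": -1.8645, "beta_log_height": 0.0, "beta_log_age": 0.0, "spline": null, "spline_declared": false}
    },
    "fev1_fvc": {
      "family": "BCCG",
      "mu": {"link": "log", "intercept": 1.968086, "beta_log_height": -0.416269, "beta_log_age": 0.009565, "spline": null, "spline_declared": true},
      "sigma": {"link": "log", "intercept": -3.7224, "beta_log_height": 0.0, "beta_log_age": 0.3145, "spline": null, "spline_declared": true},
      "nu": {"link": "identity", "intercept": 1.0, "beta_log_height": 0.0, "beta_log_age": 0.0, "spline": null, "spline_declared": false}
    },
    "fef2575": {
      "family": "BCPE",
      "mu": {"link": "log", "intercept": -3.5388, "beta_log_height": 1.049, "beta_log_age": -0.1505, "spline": null, "spline_declared": true},
      "sigma": {"link": "log", "intercept": -3.9378, "beta_log_height": 0.0, "beta_log_age": 0.6482, "spline": null, "spline_declared": true},
      "nu": {"link": "identity", "intercept": -7.711, "beta_log_height": 0.0, "beta_log_age": 1.956, "spline": null, "spline_declared": false},
      "tau": {"link": "log", "intercept": 0.6736, "beta_log_height": 0.0, "beta_log_age": 0.637, "spline": null, "spline_declared": false}
    }
  }
}
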