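{
  "schema_version": 1,
  "name": "ISE-male",
  "sex": "male",
  "valid_age_range": [18.0, 70.0],
  "acknowledge_missing_splines": true,
  "indices": {
    "fev1": {
      "family": "BCCG",
      "mu": {"link": "identity", "intercept": -28.157, "beta_log_height": 6.8055, "beta_log_age": -0.8566, "spline": null, "spline_declared": true},
      "sigma": {"link": "log", "intercept": -1.8308, "beta_log_height": 0.0, "beta_log_age": -0.1192, "spline": null, "spline_declared": true},
      "nu": {"link": "identity", "intercept": -2.3096, "beta_log_height": 0.0, "beta_log_age": 0.3956, "spline": null, "spline_declared": false}
    },
    "fvc": {
      "family": "BCCG",
      "mu": {"link": "log", "intercept": -8.37157, "beta_log_height": 2.05757, "beta_log_age": -0.20888, "spline": null, "spline_declared": false},
      "sigma": {"link": "log", "intercept": -2.14143, "beta_log_height": 0.0, "beta_log_age": 0.0, "spline": null, "spline_declared": false},
      "nu": {"link": "identity", "intercept": -1.8044, "beta_log_height": 0.0, "beta_log_age": 0.0, "spline": null, "spline_declared": false}
    },
    "fev1_fvc": {
      "family": "BCCG",
      "mu": {"link": "identity", "intercept": 1.458485, "beta_log_height": -0.111511, "beta_log_age": -0.007171, "spline": null, "spline_declared": true},
      "sigma": {"link": "log", "intercept": -3.39125, "beta_log_height": 0.0, "beta_log_age": 0.15846, "spline": null, "spline_declared": true},
      "nu": {"link": "identity", "intercept": 0.4028, "beta_log_height": 0.0, "beta_log_age": -0.4593, "spline": null, "spline_declared": false}
    },
    "fef2575": {
      "family": "BCCG",
      "mu": {"link": "log", "intercept": -4.20476, "beta_log_height": 1.23963, "beta_log_age": -0.206, "spline": null, "spline_declared": true},
      "sigma": {"link": "log", "intercept": -2.42013, "beta_log_height": 0.0, "beta_log_age": 0.18673, "spline": null, "spline_declared": true},
      "nu": {"link": "identity", "intercept": -4.8567, "beta_log_height": 0.0, "beta_log_age": 1.0254, "spline": null, "spline_declared": false}
    }
  }
}
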