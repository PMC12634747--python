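{
  "intercept": 8.376574559231825,
  "coefficients": {
    "dmap_std": -0.3141404228710667,
    "glcm_correlation": 1.438988041473833,
    "age": -0.1564062843792018
  },
  "selected_feature_names": [
    "dmap_std",
    "glcm_correlation",
    "age"
  ],
  "log_likelihood": -466.459568926788,
  "aic": 940.919137853576,
  "n_fit": 800,
  "feature_means": {
    "dmap_std": 0.47932582646308913,
    "glcm_correlation": 0.9438443224559684,
    "age": 61.34707575397835
  },
  "feature_stds": {
    "dmap_std": 0.7237866995217099,
    "glcm_correlation": 0.01590054603427274,
    "age": 6.574610789533601
  },
  "intercept_std": -0.010888541768375224,
  "coefficients_std": {
    "dmap_std": -0.22737065985620364,
    "glcm_correlation": 0.02288069559622265,
    "age": -1.0283104448303608
  },
  "standard_errors_std": {
    "dmap_std": 0.09657658958509313,
    "glcm_correlation": 0.09689847728737298,
    "age": 0.08908538156833017
  },
  "separation_flag": false,
  "converged": true,
  "seed": 20250926
}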