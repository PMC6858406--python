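{
  "hip_extensors": {
    "constant": 1087.037,
    "constant_se": 410.022,
    "constant_ci95": [193.676, 1980.398],
    "constant_p": "0.021",
    "slope": 64.946,
    "slope_se": 12.554,
    "slope_ci95": [37.594, 92.298],
    "slope_p": "<0.001",
    "r2": 0.690,
    "adj_r2": 0.665,
    "see_cm3": 283.01,
    "see_pct": 8.92,
    "cv_residual_cm3": -347.32,
    "cv_residual_pct": 11.28,
    "durbin_watson": 1.67,
    "dev_n": 14,
    "cv_n": 3,
    "dev_mv_mean": 3171.9,
    "dev_mv_sd": 488.7,
    "cv_mv_mean": 3078.8,
    "systematic_error_caveat": false
  },
  "knee_extensors": {
    "constant": 996.168,
    "constant_se": 257.349,
    "constant_ci95": [429.747, 1562.588],
    "constant_p": "0.003",
    "slope": 4.664,
    "slope_se": 0.905,
    "slope_ci95": [2.673, 6.655],
    "slope_p": "<0.001",
    "r2": 0.707,
    "adj_r2": 0.681,
    "see_cm3": 121.10,
    "see_pct": 5.24,
    "cv_residual_cm3": 20.11,
    "cv_residual_pct": 0.95,
    "durbin_watson": 2.32,
    "dev_n": 13,
    "cv_n": 3,
    "dev_mv_mean": 2311.6,
    "dev_mv_sd": 214.3,
    "cv_mv_mean": 2110.32,
    "systematic_error_caveat": false
  },
  "knee_flexors": {
    "constant": 1199.444,
    "constant_se": 161.753,
    "constant_ci95": [843.428, 1555.461],
    "constant_p": "<0.001",
    "slope": 318.147,
    "slope_se": 128.860,
    "slope_ci95": [34.528, 601.766],
    "slope_p": "0.031",
    "r2": 0.357,
    "adj_r2": 0.298,
    "see_cm3": 125.37,
    "see_pct": 7.89,
    "cv_residual_cm3": -42.72,
    "cv_residual_pct": -2.66,
    "durbin_watson": 2.18,
    "dev_n": 13,
    "cv_n": 3,
    "dev_mv_mean": 1589.5,
    "dev_mv_sd": 149.6,
    "cv_mv_mean": 1607.2,
    "systematic_error_caveat": true
  },
  "ankle_plantarflexors": {
    "constant": 878.606,
    "constant_se": 140.417,
    "constant_ci95": [572.662, 1184.549],
    "constant_p": "<0.001",
    "slope": 0.553,
    "slope_se": 0.201,
    "slope_ci95": [0.115, 0.991],
    "slope_p": "0.018",
    "r2": 0.387,
    "adj_r2": 0.336,
    "see_cm3": 134.91,
    "see_pct": 10.78,
    "cv_residual_cm3": 92.44,
    "cv_residual_pct": 6.37,
    "durbin_watson": 1.44,
    "dev_n": 14,
    "cv_n": 4,
    "dev_mv_mean": 1252.0,
    "dev_mv_sd": 165.5,
    "cv_mv_mean": 1451.5,
    "systematic_error_caveat": true
  }
}
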