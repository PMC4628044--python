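{
  "HuCCA-1": {
    "intercept": 0.8738,
    "coefficients": {
      "R5e+": -84.0157,
      "nArCOOR": 1.0288
    },
    "n": 13,
    "r_tr": 0.9597,
    "rmse_tr": 0.1603,
    "r_cv": 0.8957,
    "rmse_cv": 0.2562,
    "citation": "Table 3 / Eq. 1"
  },
  "HepG2": {
    "intercept": -1.7524,
    "coefficients": {
      "RDF105m": 0.0784,
      "MATS7m": 5.1878
    },
    "n": 24,
    "r_tr": 0.7537,
    "rmse_tr": 0.4006,
    "r_cv": 0.6724,
    "rmse_cv": 0.4526,
    "citation": "Table 3 / Eq. 2",
    "note": "Running-text equation prints intercept +1.7524; Table 3 prints -1.7524. The negative sign is used: it is the only one consistent with the predicted pIC50 range for positive RDF105m/MATS7m."
  },
  "A549": {
    "intercept": -1.7829,
    "coefficients": {
      "MATS8v": 1.5979,
      "nArCOOR": 0.9251
    },
    "n": 16,
    "r_tr": 0.8673,
    "rmse_tr": 0.239,
    "r_cv": 0.5958,
    "rmse_cv": 0.4211,
    "citation": "Table 3 / Eq. 3"
  },
  "MOLT-3": {
    "intercept": -5.6832,
    "coefficients": {
      "Lop": 1.0649,
      "R7m": 10.3977
    },
    "n": 20,
    "r_tr": 0.8936,
    "rmse_tr": 0.1714,
    "r_cv": 0.843,
    "rmse_cv": 0.207,
    "citation": "Table 3 / Eq. 4"
  }
}
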