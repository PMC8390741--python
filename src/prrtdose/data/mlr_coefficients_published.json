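{
  "description": "Published single-time-point regression coefficient sets for Lu-177 DOTA-TATE dosimetry, by target and training-time tag. Unit contract: concentration mCi/cc, time h, dose mGy.",
  "unit_contract": "mCi/cc",
  "targets": {
    "kidneys": {
      "t1": {"kind": "solid", "alpha0": 12.01, "alpha1": 0.91, "alpha2": 0.0153, "r2_train": 0.85, "n_train": 40},
      "t2": {"kind": "solid", "alpha0": 11.87, "alpha1": 0.85, "alpha2": 0.0117, "r2_train": 0.98, "n_train": 36},
      "t3": {"kind": "solid", "alpha0": 11.83, "alpha1": 0.83, "alpha2": 0.0103, "r2_train": 0.95, "n_train": 40},
      "t1t2t3": {"kind": "solid", "alpha0": 11.86, "alpha1": 0.85, "alpha2": 0.0111, "r2_train": 0.94, "n_train": 116}
    },
    "tumors": {
      "t1": {"kind": "solid", "alpha0": 13.27, "alpha1": 1.03, "alpha2": -0.0105, "r2_train": 0.97, "n_train": 39},
      "t2": {"kind": "solid", "alpha0": 12.90, "alpha1": 0.99, "alpha2": 0.0070, "r2_train": 0.99, "n_train": 35},
      "t3": {"kind": "solid", "alpha0": 12.76, "alpha1": 0.97, "alpha2": 0.0081, "r2_train": 0.99, "n_train": 39},
      "t1t2t3": {"kind": "solid", "alpha0": 12.80, "alpha1": 0.99, "alpha2": 0.0086, "r2_train": 0.99, "n_train": 113}
    },
    "liver": {
      "t1": {"kind": "solid", "alpha0": 12.37, "alpha1": 0.96, "alpha2": 0.0205, "r2_train": 0.88, "n_train": 40},
      "t2": {"kind": "solid", "alpha0": 11.86, "alpha1": 0.86, "alpha2": 0.0111, "r2_train": 0.97, "n_train": 36},
      "t3": {"kind": "solid", "alpha0": 12.57, "alpha1": 0.91, "alpha2": 0.0077, "r2_train": 0.97, "n_train": 40},
      "t1t2t3": {"kind": "solid", "alpha0": 12.26, "alpha1": 0.90, "alpha2": 0.0090, "r2_train": 0.92, "n_train": 116}
    },
    "spleen": {
      "t1": {"kind": "solid", "alpha0": 12.21, "alpha1": 1.00, "alpha2": 0.0336, "r2_train": 0.97, "n_train": 37},
      "t2": {"kind": "solid", "alpha0": 12.48, "alpha1": 0.93, "alpha2": 0.0094, "r2_train": 0.99, "n_train": 33},
      "t3": {"kind": "solid", "alpha0": 12.52, "alpha1": 0.94, "alpha2": 0.0090, "r2_train": 0.99, "n_train": 37},
      "t1t2t3": {"kind": "solid", "alpha0": 12.51, "alpha1": 0.95, "alpha2": 0.0094, "r2_train": 0.98, "n_train": 107}
    },
    "bone_marrow": {
      "t1": {"kind": "marrow", "theta_bm_bm": 1868, "theta_bm_rm": 319, "beta0": 4.26, "beta1": 1.07, "beta2": 0.0241, "r2_train": 0.78, "n_train": 40},
      "t3": {"kind": "marrow", "theta_bm_bm": 1889, "theta_bm_rm": 315, "beta0": 5.03, "beta1": 0.82, "beta2": 0.0069, "r2_train": 0.92, "n_train": 40},
      "t1t3": {"kind": "marrow", "theta_bm_bm": 1879, "theta_bm_rm": 316, "beta0": 4.59, "beta1": 0.90, "beta2": 0.0101, "r2_train": 0.83, "n_train": 80}
    }
  }
}
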