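{
  "description": "SYNTHETIC dose-factor table. Proprietary phantom S-value libraries cannot be redistributed, so these are physically plausible stand-ins for Lu-177: self dose factors follow DF = theta/m_phantom with a self-coupling theta = 0.0773 mGy*kg/(MBq*h) derived from the mean beta energy (~134 keV, absorbed fraction ~1); photon cross terms are small illustrative values. Marrow couplings theta_bm_bm/theta_bm_rm are in mGy per (mCi*h/cc).",
  "phantoms": {
    "adult_male": {
      "organ_masses_kg": {"kidneys": 0.31, "liver": 1.81, "spleen": 0.183, "remainder": 57.0},
      "organ_self_theta": {"kidneys": 0.0773, "liver": 0.0773, "spleen": 0.0773, "remainder": 0.0773},
      "theta_bm_bm": 1889.0,
      "theta_bm_rm": 315.0,
      "dose_factors": [
        {"source": "kidneys", "target": "kidneys", "DF": 6.9265e-05},
        {"source": "liver", "target": "liver", "DF": 1.1863e-05},
        {"source": "spleen", "target": "spleen", "DF": 1.1734e-04},
        {"source": "liver", "target": "kidneys", "DF": 2.8e-08},
        {"source": "spleen", "target": "kidneys", "DF": 5.5e-08},
        {"source": "kidneys", "target": "liver", "DF": 2.8e-08},
        {"source": "spleen", "target": "liver", "DF": 9.0e-09},
        {"source": "kidneys", "target": "spleen", "DF": 5.5e-08},
        {"source": "liver", "target": "spleen", "DF": 9.0e-09},
        {"source": "remainder", "target": "kidneys", "DF": 4.0e-09},
        {"source": "remainder", "target": "liver", "DF": 4.0e-09},
        {"source": "remainder", "target": "spleen", "DF": 4.0e-09}
      ]
    },
    "adult_female": {
      "organ_masses_kg": {"kidneys": 0.275, "liver": 1.4, "spleen": 0.15, "remainder": 47.0},
      "organ_self_theta": {"kidneys": 0.0773, "liver": 0.0773, "spleen": 0.0773, "remainder": 0.0773},
      "theta_bm_bm": 1889.0,
      "theta_bm_rm": 315.0,
      "dose_factors": [
        {"source": "kidneys", "target": "kidneys", "DF": 7.8081e-05},
        {"source": "liver", "target": "liver", "DF": 1.5337e-05},
        {"source": "spleen", "target": "spleen", "DF": 1.4315e-04},
        {"source": "liver", "target": "kidneys", "DF": 3.4e-08},
        {"source": "spleen", "target": "kidneys", "DF": 6.6e-08},
        {"source": "kidneys", "target": "liver", "DF": 3.4e-08},
        {"source": "spleen", "target": "liver", "DF": 1.1e-08},
        {"source": "kidneys", "target": "spleen", "DF": 6.6e-08},
        {"source": "liver", "target": "spleen", "DF": 1.1e-08},
        {"source": "remainder", "target": "kidneys", "DF": 5.0e-09},
        {"source": "remainder", "target": "liver", "DF": 5.0e-09},
        {"source": "remainder", "target": "spleen", "DF": 5.0e-09}
      ]
    }
  }
}
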