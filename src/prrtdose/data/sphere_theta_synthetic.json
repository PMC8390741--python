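{
  "description": "SYNTHETIC unit-density-sphere self-coupling table for tumor dosimetry: theta(m) in mGy*kg/(MBq*h) versus sphere mass in kg. Values approach the non-penetrating-emission limit 0.0773 for large spheres and fall off at small masses where beta escape reduces the absorbed fraction. Illustrative stand-in for a published sphere-model library; piecewise-linear interpolation in mass, no extrapolation.",
  "mass_kg": [0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0, 5.0],
  "theta": [0.0580, 0.0685, 0.0716, 0.0755, 0.0764, 0.0771, 0.0772, 0.0773]
}
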