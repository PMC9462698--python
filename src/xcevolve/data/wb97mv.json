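{
  "name": "wB97M-V semilocal enhancement factors (power series in w and u)",
  "version": "1.0",
  "notes": "Term key 'ij' multiplies w^i * u^j. Coefficients transcribed from the published wB97M-V parameterization; gamma values define u = gamma*x^2/(1+gamma*x^2) per channel.",
  "gamma": {"x": 0.004, "css": 0.2, "cos": 0.006},
  "term_subsets": {
    "x": ["00", "10", "01"],
    "css": ["00", "10", "20", "43", "04"],
    "cos": ["00", "10", "20", "60", "21", "61"]
  },
  "coefficients": {
    "x": {"00": 0.85, "10": 1.007, "01": 0.259},
    "css": {"00": 0.443, "10": -1.437, "20": -4.535, "43": -3.39, "04": 4.278},
    "cos": {"00": 1.0, "10": 1.358, "20": 2.924, "60": -8.812, "21": -1.39, "61": 9.142}
  }
}
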