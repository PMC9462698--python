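{
  "name": "GAS22 semilocal enhancement factors",
  "version": "1.0",
  "notes": "Closed-form meta-GGA enhancement factors; u = gamma*x^2/(1+gamma*x^2). The opposite-spin channel carries an x^(3/2) term (x_exponent below).",
  "x": {
    "gamma": 0.00384,
    "c0": 0.862,
    "c_u": 0.937,
    "c_w": 0.318
  },
  "css": {
    "gamma": 0.469,
    "c_u": 1.0,
    "c_w": -4.108,
    "c_w2": -5.242,
    "c_u6": -1.766,
    "c_w4u6": 7.538
  },
  "cos": {
    "c0": 0.805,
    "c_w2": 7.989,
    "c_w6": -7.548,
    "c_w6x": 2.001,
    "c_w2x": -1.761,
    "x_exponent": "3/2"
  }
}
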