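{
  "dmu0_x_D": 5.53,
  "dmu0_y_D": -3.17,
  "dalpha_xx_A3": -61.3,
  "dalpha_yy_A3": 6.9,
  "nu0_cm": 16260.0
}
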