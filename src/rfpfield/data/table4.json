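{
  "B_s": 1.5e9,
  "dG_vac_kcal_mol": -7.9,
  "lambda_kcal_mol": 21.9,
  "q_esu": 1.54e-10,
  "dx_A": 6.7,
  "dy_A": -0.67,
  "eta": -0.1
}
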