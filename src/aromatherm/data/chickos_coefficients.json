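{
  "version": "chickos-acree-1",
  "comment": "Affine heat-capacity corrections c = a + b_cp_cr*Cp(cr) + b_cp_l*Cp(l), Cp in J/mol/K; dH(T_target) = dH(T_obs) + c*(T_obs - T_target)/1000 in kJ/mol.",
  "fusion": {"a": -9.83, "b_cp_cr": 0.15, "b_cp_l": -0.26},
  "vaporization": {"a": 10.58, "b_cp_cr": 0.0, "b_cp_l": 0.26},
  "sublimation": {"a": 0.75, "b_cp_cr": 0.15, "b_cp_l": 0.0}
}
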