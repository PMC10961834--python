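{
  "compound": {
    "name": "trimellitic acid",
    "formula": {"C": 9, "H": 6, "O": 6},
    "M_g_per_mol": 210.140,
    "density_g_per_cm3": 1.580,
    "cp_massic_J_per_gK": 1.18,
    "du_dp_J_per_gMPa": -0.2
  },
  "calibration": {
    "eps_calor_kJK": 10.1351,
    "u_eps_calor_kJK": 0.0025,
    "du_oil_kJ_per_g": -46.2385,
    "u_du_oil_kJ_per_g": 0.0066,
    "du_cotton_kJ_per_g": -16.9452,
    "u_du_cotton_kJ_per_g": 0.0042,
    "dH_HNO3_kJ_per_mol": -59.7,
    "T_ref_K": 298.15
  },
  "references": {
    "dfH_CO2_g_kJ_per_mol": -393.51,
    "u_dfH_CO2_g_kJ_per_mol": 0.13,
    "dfH_H2O_l_kJ_per_mol": -285.83,
    "u_dfH_H2O_l_kJ_per_mol": 0.04,
    "R_J_per_molK": 8.314462618
  },
  "chickos_inputs": {
    "comment": "Fusion enthalpy measured by DSC at T_fus; Cp(l) is not printed by the source and is back-solved from the reported 298.15 K fusion value (synthetic stand-in, see docs/methods.md).",
    "fusion": {"dH_kJ_per_mol": 56.6, "u_kJ_per_mol": 1.6, "T_obs_K": 521.8},
    "Cp_cr_J_per_molK": 247.9652,
    "Cp_l_J_per_molK": 297.9
  },
  "route_inputs": {
    "comment": "Reported 298.15 K route values; the raw mass-loss traces behind them are not published, so they enter the cycle as inputs.",
    "vaporization": {"value": 97.1, "u": 1.4, "T": 298.15},
    "sublimation_direct": {"value": 144.8, "u": 5.4, "T": 298.15}
  },
  "expected": {
    "du_mean_kJ_per_g": -15.3489,
    "du_mean_tol": 0.0005,
    "du_runs_tol": 0.002,
    "dcU_m_kJ_per_mol": -3225.4,
    "dcH_m_kJ_per_mol": -3221.7,
    "dfH_cr_kJ_per_mol": -1177.4,
    "table4_tol": 0.1,
    "fusion_298_kJ_per_mol": 45.4,
    "fusion_tol": 0.5,
    "sublimation_routeA_kJ_per_mol": 142.5,
    "sublimation_routeA_u": 2.4,
    "dfH_g_routeA_kJ_per_mol": -1034.9,
    "dfH_g_routeA_u": 3.8,
    "dfH_g_routeB_kJ_per_mol": -1032.6,
    "dfH_g_routeB_u": 6.1,
    "cycle_tol": 0.1
  }
}
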