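{
  "description": "Printed thermal-stability measurements of alpha-actinin-1 SR4 and titin I27 tandem-domain constructs: measured inputs (force, temperature, unfolded probability p, conformational term dPhi) and the published derived quantities (dG(F), dG0, Fc) they imply. Energies in kBT, forces in pN, temperatures in Celsius.",
  "columns": [
    {"domain": "SR4", "n_residues": 104, "rod_length_nm": 5.0,
     "force": 5.7, "force_se": 0.57, "temperature": 23,
     "p": 0.091, "p_se": 0.002, "dPhi": 10.90, "dPhi_se": 2.03,
     "dG_printed": -2.30, "dG_se_printed": 0.02,
     "dG0_printed": -13.2, "dG0_se_printed": 2.0,
     "Fc_printed": 6.3, "Fc_se_printed": 0.5},
    {"domain": "SR4", "n_residues": 104, "rod_length_nm": 5.0,
     "force": 5.7, "force_se": 0.57, "temperature": 27,
     "p": 0.283, "p_se": 0.004, "dPhi": 10.38, "dPhi_se": 2.01,
     "dG_printed": -0.93, "dG_se_printed": 0.02,
     "dG0_printed": -11.3, "dG0_se_printed": 2.0,
     "Fc_printed": 6.0, "Fc_se_printed": 0.6},
    {"domain": "SR4", "n_residues": 104, "rod_length_nm": 5.0,
     "force": 5.7, "force_se": 0.57, "temperature": 29,
     "p": 0.531, "p_se": 0.005, "dPhi": 10.31, "dPhi_se": 1.99,
     "dG_printed": 0.12, "dG_se_printed": 0.02,
     "dG0_printed": -10.2, "dG0_se_printed": 2.0,
     "Fc_printed": 5.7, "Fc_se_printed": 0.6},
    {"domain": "SR4", "n_residues": 104, "rod_length_nm": 5.0,
     "force": 5.7, "force_se": 0.57, "temperature": 31,
     "p": 0.722, "p_se": 0.008, "dPhi": 10.15, "dPhi_se": 1.96,
     "dG_printed": 0.95, "dG_se_printed": 0.04,
     "dG0_printed": -9.2, "dG0_se_printed": 2.0,
     "Fc_printed": 5.4, "Fc_se_printed": 0.6},
    {"domain": "I27", "n_residues": 89, "rod_length_nm": 4.4,
     "force": 4.5, "force_se": 0.45, "temperature": 23,
     "p": 0.131, "p_se": 0.004, "dPhi": 6.44, "dPhi_se": 1.1,
     "dG_printed": -1.89, "dG_se_printed": 0.05,
     "dG0_printed": -8.3, "dG0_se_printed": 1.0,
     "Fc_printed": 5.4, "Fc_se_printed": 0.4},
    {"domain": "I27", "n_residues": 89, "rod_length_nm": 4.4,
     "force": 3.5, "force_se": 0.35, "temperature": 37,
     "p": 0.272, "p_se": 0.004, "dPhi": 3.95, "dPhi_se": 0.7,
     "dG_printed": -0.98, "dG_se_printed": 0.04,
     "dG0_printed": -4.9, "dG0_se_printed": 0.7,
     "Fc_printed": 3.9, "Fc_se_printed": 0.3}
  ]
}
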