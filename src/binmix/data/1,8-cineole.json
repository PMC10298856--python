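{
  "name": "1,8-cineole",
  "molar_mass": 154.25,
  "Tc": 661.12,
  "Pc": 3.019,
  "omega": 0.338,
  "Tb": 449.6,
  "molar_volume_table": [
    [278.15, 164.6e-6],
    [283.15, 165.3e-6],
    [288.15, 166.1e-6],
    [293.15, 166.9e-6],
    [298.15, 167.7e-6],
    [303.15, 168.5e-6],
    [308.15, 169.2e-6],
    [313.15, 170.0e-6],
    [318.15, 170.9e-6],
    [323.15, 171.7e-6]
  ],
  "antoine": null,
  "B_ref": -5490.0e-6,
  "T_ref": 325.0,
  "cubic_params": {
    "PRM": {"p1": -0.003518, "c_over_b": -0.086491},
    "PRSV": {"kappa1": 0.007355, "c_over_b": -0.086427}
  },
  "saft_params": {
    "m": 4.842,
    "v00": 0.0178,
    "u0_over_k": 263.43,
    "e_over_k": 10.0,
    "kappa_AB": 0.0,
    "eps_AB_over_k": 0.0,
    "scheme": "none"
  }
}
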