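{
  "name": "2-propanol",
  "molar_mass": 60.096,
  "Tc": 508.3,
  "Pc": 4.760,
  "omega": 0.665,
  "Tb": 355.4,
  "molar_volume_table": [
    [278.15, 75.35e-6],
    [283.15, 75.70e-6],
    [288.15, 76.12e-6],
    [293.15, 76.52e-6],
    [298.15, 76.93e-6],
    [303.15, 77.35e-6],
    [308.15, 77.78e-6],
    [313.15, 78.23e-6],
    [318.15, 78.66e-6],
    [323.15, 79.15e-6]
  ],
  "antoine": {"A": 17.6939, "B": 4114.55, "C": 39.969, "pressure_unit": "kPa"},
  "B_ref": -1810.0e-6,
  "T_ref": 325.0,
  "cubic_params": {
    "PRM": {"p1": -0.256223, "c_over_b": 0.039731},
    "PRSV": {"kappa1": 0.166735, "c_over_b": 0.039468}
  },
  "saft_params": {
    "m": 3.249,
    "v00": 0.0120,
    "u0_over_k": 202.94,
    "e_over_k": 10.0,
    "kappa_AB": 0.0210,
    "eps_AB_over_k": 2670.0,
    "scheme": "2B"
  }
}
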