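"""Physical constants and unit conventions.

Everything inside the package is SI: pressures in Pa, temperatures in K,
molar volumes in m3/mol, molar energies in J/mol.  Conversions to the
conventional reporting units (kPa for Antoine constants, cm3/mol for excess
volumes, L/mol for SAFT segment volumes) happen only at I/O boundaries.
"""

#: Universal gas constant, J mol^-1 K^-1 (CODATA 2018).
R = 8.314462618

#: Reference temperature (K) at which the second virial coefficients are
#: evaluated; the vapor phase of the static apparatus was thermostatted here,
#: so B11, B22 and delta12 are treated as temperature-independent constants.
T_REF_VIRIAL = 325.0

#: kPa -> Pa
KPA = 1.0e3

#: cm3/mol -> m3/mol
CM3_PER_MOL = 1.0e-6

#: L/mol -> m3/mol
L_PER_MOL = 1.0e-3
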