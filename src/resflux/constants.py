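"""Physical constants shared across modules (SI unless noted)."""

#: Universal gas constant, J mol^-1 K^-1
R_GAS = 8.314462618

#: Molar mass of CH4, g mol^-1
MOLAR_MASS_CH4 = 16.04

#: Molar mass of carbon, g mol^-1
MOLAR_MASS_C = 12.011

#: Molar volume of an ideal gas at STP (0 degC, 1 atm), L mol^-1
MOLAR_VOLUME_STP = 22.414

#: Gravitational acceleration, m s^-2
GRAVITY = 9.81

#: Freshwater density used for hydrostatic pressure, kg m^-3
#: (temperature dependence is < 0.3 % over 0-30 degC)
RHO_WATER = 1000.0

#: Standard atmospheric pressure, Pa
P_ATM_STANDARD = 101325.0
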