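"""Physical constants and unit-conversion factors shared across modules."""

#: Ideal-gas constant, L atm mol-1 K-1.
R_GAS_L_ATM = 0.0820574

#: 0 degC in kelvin.
T0_K = 273.15

#: Molar mass of carbon, mg mmol-1 (equivalently g mol-1).
MOLAR_MASS_C = 12.011

#: Molar masses for mg -> mmol conversion of titrated carbonate species, g mol-1.
MOLAR_MASS_HCO3 = 61.017
MOLAR_MASS_CO3 = 60.009

#: Molar mass of O2, g mol-1.
MOLAR_MASS_O2 = 31.9988

#: cm h-1 -> m d-1 (24 h day).
CM_PER_H_TO_M_PER_D = 0.24

#: Default dry-air mole fractions (dimensionless).
DEFAULT_CO2_MOLE_FRACTION = 410e-6
DEFAULT_CH4_MOLE_FRACTION = 1.87e-6

#: Scale height of the isothermal barometric formula, m.
BAROMETRIC_SCALE_HEIGHT_M = 8400.0

#: Molar volume of an ideal gas at STP, L mol-1 (Bunsen -> molar solubility).
MOLAR_VOLUME_STP = 22.414
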