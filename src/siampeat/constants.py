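"""Isotope constants shared across the package."""

#: Mass difference between 13C and 12C, Da.
C13_MASS_DIFF = 1.0033548

#: Natural abundance of 13C (fraction of carbon atoms).
P_NATURAL_13C = 0.0107

#: 13C/12C isotope ratio of the VPDB standard (dimensionless).
R_VPDB = 0.0111802

#: delta-13C (permil vs VPDB) of the CO2 standard gas used for jar flushing.
DELTA_STANDARD_GAS = -33.8
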