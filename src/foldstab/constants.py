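"""Physical constants used across the energetics modules."""

#: Ideal gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.987204e-3

#: Additive offset from degrees Celsius to kelvin.
CELSIUS_OFFSET = 273.15
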