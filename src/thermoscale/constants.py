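"""Physical constants and fixed unit conversions used throughout the package."""

#: Boltzmann constant in electron-volts per Kelvin (CODATA).
BOLTZMANN_EV_PER_K = 8.617333e-5

#: Energy released per micromole of O2 consumed (J per umol O2), the oxyjoule
#: equivalent appropriate for a mixed-substrate detritivore diet.
OXYJOULE_J_PER_UMOL = 0.45

#: Hours per day; VO2 is measured per hour, SMR is reported per day.
HOURS_PER_DAY = 24.0

#: Mole fraction of O2 in dry air.
O2_MOLE_FRACTION = 0.20946

#: Standard atmospheric pressure in torr.
ATM_TORR = 760.0

#: Molar volume of O2 at STP (L/mol); converts mL O2 per L to umol per L.
O2_MOLAR_VOLUME_L = 0.022391

#: Celsius-to-Kelvin offset.
KELVIN_OFFSET = 273.15


def celsius_to_kelvin(temp_c: float) -> float:
    return temp_c + KELVIN_OFFSET
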