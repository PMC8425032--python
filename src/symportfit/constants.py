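"""Physical constants and unit conventions used package-wide.

Units are fixed throughout the package: voltage in mV, current in nA,
time in ms, charge in nC, sugar concentration in mM, proton concentration
in nM.  Conversions to SI happen only inside exponents (mV -> V) and at
I/O boundaries.  The nA/nC pair makes the turnover ratio |Imax|/|Qmax|
come out directly in s^-1.
"""

FARADAY = 96485.332
"""Faraday constant, C mol^-1."""

GAS_CONSTANT = 8.3145
"""Molar gas constant, J mol^-1 K^-1."""

DEFAULT_TEMPERATURE = 293.15
"""Default recording temperature, K (20 degC)."""

OD_TO_CDW_DEFAULT = 0.252
"""Measured conversion between optical density and cell dry weight, mg_CDW per OD unit."""


def thermal_voltage_mv(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """RT/F in millivolts (about 25.26 mV at 293.15 K)."""
    return 1000.0 * GAS_CONSTANT * temperature / FARADAY
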