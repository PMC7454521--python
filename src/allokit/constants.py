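"""Physical constants and unit conventions.

Energies are in kcal/mol throughout, denaturant concentrations in molar,
rates in s^-1, substrate concentrations in uM, time in hours (growth) or
seconds (enzymology).
"""

#: Gas constant in kcal/(mol*K).
GAS_CONSTANT_KCAL = 0.0019872

#: Default assay temperature, 30 degC, at which melts equilibrate and
#: kinetic and growth assays are run.
DEFAULT_TEMPERATURE_K = 303.15


def rt(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """RT in kcal/mol at the given absolute temperature."""
    if temperature_k <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return GAS_CONSTANT_KCAL * temperature_k
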