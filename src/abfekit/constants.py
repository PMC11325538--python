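"""Physical constants and unit conventions shared across the package.

Energies are kcal/mol, distances Å, temperatures K. Angle math is done in
radians internally; user-facing references and reports are in degrees.
"""

import math

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL: float = 1.987204259e-3

#: Default absolute temperature, K.
T_DEFAULT: float = 298.15

#: Standard-state volume per molecule at 1 M, Å^3 (1 / (1 mol/L * N_A)).
V0_STANDARD: float = 1660.5392

#: Orientational volume of an unrestrained rigid body, rad^3.
ORIENTATIONAL_VOLUME: float = 8.0 * math.pi**2


def rt(temperature: float = T_DEFAULT) -> float:
    """Thermal energy RT in kcal/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature
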