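"""Internal unit system and physical constants.

The package works in Å (length), ps (time), kDa (mass), elementary charges (e)
and kT at the force-field reference temperature (energy).  The Boltzmann
constant in this unit system fixes the conversion between reduced energies and
mechanical units (kDa Å²/ps²).
"""

from scipy import constants as _c

#: Boltzmann constant in kDa Å² ps⁻² K⁻¹.
KB = _c.Boltzmann / (1e3 * _c.atomic_mass * (1e-10 / 1e-12) ** 2)

#: One kDa expressed in grams.
KDA_TO_G = 1e3 * _c.atomic_mass * 1e3

#: One litre in Å³.
LITRE_TO_A3 = 1e-3 * 1e30

#: Conversion from centipoise to kDa Å⁻¹ ps⁻¹ (viscosity in internal units).
#: 1 cP = 1e-3 Pa s = 1e-3 kg m⁻¹ s⁻¹.
CP_TO_INTERNAL = 1e-3 / (1e3 * _c.atomic_mass) * 1e-10 * 1e-12


def kt_to_mechanical(temperature: float) -> float:
    """Energy of 1 kT at *temperature* (K) in kDa Å² ps⁻²."""
    return KB * temperature
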