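"""Unit system and conversion constants.

Internal units throughout the package: kcal/mol (energy), Angstrom (length),
ps (time), Kelvin (temperature).  Metadynamics hill heights are quoted in
kJ/mol in much of the literature and squared path distances in nm^2; both are
converted at the I/O boundary only.
"""

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872041

#: 1 kJ/mol in kcal/mol
KJ_TO_KCAL = 0.239005736
KCAL_TO_KJ = 1.0 / KJ_TO_KCAL

#: 1 kcal/mol/A in piconewton
KCAL_PER_MOL_ANGSTROM_TO_PN = 69.4786
PN_TO_KCAL_PER_MOL_ANGSTROM = 1.0 / KCAL_PER_MOL_ANGSTROM_TO_PN

#: squared-distance conversions (1 nm^2 = 100 A^2)
NM2_TO_A2 = 100.0
A2_TO_NM2 = 0.01


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol at the given temperature in K."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
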