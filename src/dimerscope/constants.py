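"""Physical constants and unit conventions.

Internal units throughout the package: lengths in nm, times in ns,
energies in kJ/mol, angles in degrees in the interval (-180, 180].
"""

#: Boltzmann constant in kJ/mol/K.
KB = 0.0083145

#: Simulation temperature of the coarse-grained systems (K).
DEFAULT_TEMPERATURE = 310.0


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kJ/mol (2.5775 kJ/mol at 310 K)."""
    return KB * temperature
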