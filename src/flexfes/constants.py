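"""Physical constants and unit conversions.

Internal unit system: lengths in nm, times in ns (ps inside integrators),
energies in kJ/mol. Free-energy profiles are reported in kcal/mol at the
output boundary only.
"""

#: Boltzmann constant, kJ/(mol K)
KB = 0.0083144621

#: kJ per kcal (thermochemical calorie)
KJ_PER_KCAL = 4.184

#: Default simulation temperature, K
DEFAULT_TEMPERATURE = 310.0


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol."""
    return KB * temperature


def kj_to_kcal(x):
    """Convert kJ/mol to kcal/mol."""
    return x / KJ_PER_KCAL


def kcal_to_kj(x):
    """Convert kcal/mol to kJ/mol."""
    return x * KJ_PER_KCAL
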