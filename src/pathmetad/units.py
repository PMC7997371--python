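"""Unit conventions and physical constants.

Internal units: length nm, time ps, mass g/mol, energy kcal/mol,
temperature K. The Langevin integrator converts energies to kJ/mol
internally so that (nm, ps, g/mol, kJ/mol) form a consistent set.
"""

KCAL_TO_KJ = 4.184
KB_KCAL = 0.0019872041  # kcal/mol/K
KB_KJ = KB_KCAL * KCAL_TO_KJ  # kJ/mol/K
ANGSTROM_TO_NM = 0.1
NM_TO_ANGSTROM = 10.0


def kT_kcal(temperature: float) -> float:
    """Thermal energy in kcal/mol at the given temperature (K)."""
    return KB_KCAL * temperature
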