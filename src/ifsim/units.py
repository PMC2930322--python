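"""Unit conventions and physical constants.

All lengths are in nanometres, energies in kcal/mol, charges in elementary
charges, temperatures in kelvin.  Time in the Langevin integrator is in
reduced units set by the per-bead friction coefficient (see `dynamics`).
"""

#: Boltzmann constant, kcal/mol/K.
KB_KCAL_PER_MOL_K = 0.0019872041

#: kB*T at 300 K, kcal/mol.
KT_300K = KB_KCAL_PER_MOL_K * 300.0  # 0.59616

#: Avogadro's number, 1/mol.
AVOGADRO = 6.02214076e23

#: Joules per kcal.
JOULES_PER_KCAL = 4184.0

#: Coulomb prefactor in vacuum, kcal*nm/mol/e^2  (332.0637 kcal*A/mol/e^2).
COULOMB_KCAL_NM = 33.20637


def kt(temperature: float) -> float:
    """Thermal energy kB*T in kcal/mol at the given temperature in K."""
    return KB_KCAL_PER_MOL_K * temperature
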