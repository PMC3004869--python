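"""Physical constants and unit conversions.

All coordinates are in Å, energies in kJ/mol unless a function says
kcal/mol (the nonbonded and hydrogen-bond energies follow the CHARMM /
Kabsch–Sander convention and are reported in kcal/mol).
"""

#: Gas constant, kJ mol^-1 K^-1.
R_KJ_PER_MOL_K = 8.314e-3

#: 1 kcal in kJ.
KCAL_TO_KJ = 4.184

#: Coulomb constant in kcal * Å / (mol * e^2).
COULOMB_CONSTANT_KCAL = 332.0636

#: Kabsch–Sander partial-charge product q1*q2 = 0.42 * 0.20 (e^2) and the
#: electrostatic prefactor f = 332 kcal*Å/(mol*e^2) used by their H-bond energy.
KABSCH_SANDER_PREFACTOR = 0.42 * 0.20 * 332.0

#: H-bond call threshold, kcal/mol.
HBOND_ENERGY_CUTOFF = -0.5


def rt_kj(temperature: float) -> float:
    """R*T in kJ/mol at the given temperature in K."""
    return R_KJ_PER_MOL_K * temperature
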