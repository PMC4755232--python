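"""Physical constants and unit conventions.

All quantities in the package use a single unit system: lengths in
angstrom (A), times in picoseconds (ps), energies in kcal/mol, charges in
units of the elementary charge e, temperatures in kelvin.  Diffusion
coefficients are therefore A^2/ps (translational) and rad^2/ps
(rotational), and rate constants come out in A^3/ps before conversion to
the conventional M^-1 s^-1.
"""

#: Boltzmann constant, kcal/(mol K).
KB = 0.0019872

#: Electrostatic conversion factor, kcal A / (mol e^2):  U = CC * q1*q2 / (eps * r).
COULOMB_CONSTANT = 332.064

#: Avogadro's number, 1/mol.
AVOGADRO = 6.0221e23

#: Conversion from A^3/ps to M^-1 s^-1 for bimolecular rate constants.
RATE_TO_PER_MOLAR_PER_SECOND = 6.0221e8

#: Debye screening prefactor at 298.15 K: kappa [1/A] = 0.32914 * sqrt(I [M]).
DEBYE_KAPPA_PREFACTOR = 0.32914


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB * temperature


def kappa_from_ionic_strength(ionic_strength: float) -> float:
    """Inverse Debye length (1/A) from ionic strength (mol/l) at 298.15 K."""
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    return DEBYE_KAPPA_PREFACTOR * ionic_strength ** 0.5
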