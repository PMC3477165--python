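"""Internal unit system and physical constants.

All quantities inside the package are expressed in the GROMACS-style unit
system: length nm, time ps, energy kJ/mol, mass amu (g/mol), temperature K,
charge e.  The derived force unit is kJ mol^-1 nm^-1 and velocities are
nm/ps.  PDB files (Angstrom) are converted at the I/O boundary only.
"""

# Boltzmann constant, kJ mol^-1 K^-1 (CODATA, via R = N_A * k_B)
KB = 0.00831446261815324

# Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2
COULOMB = 138.935458

# length conversions
ANGSTROM_PER_NM = 10.0
NM_PER_ANGSTROM = 0.1

# standard atomic masses (amu) for the elements this package handles
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.9994,
    "S": 32.06,
    "P": 30.974,
}


def mass_of(element: str) -> float:
    """Mass (amu) of an element symbol; unknown elements get a carbon-like
    placeholder of 12.011 so that synthetic pseudo-atoms remain usable."""
    return ELEMENT_MASSES.get(element.upper().strip(), 12.011)
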