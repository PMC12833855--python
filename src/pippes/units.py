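"""Unit conventions and physical constants.

Everything inside the package is in Hartree atomic units: lengths in bohr,
energies in hartree, masses in electron masses, time in atomic time units.
Conversion to the spectroscopist's cm^-1 happens only at reporting
boundaries.
"""

#: 1 hartree in cm^-1 (CODATA).
HARTREE_TO_CM1 = 219474.6313632

#: 1 unified atomic mass unit in electron masses.
AMU_TO_ME = 1822.888486

#: 1 bohr in Angstrom.
BOHR_TO_ANGSTROM = 0.529177210903

ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM
CM1_TO_HARTREE = 1.0 / HARTREE_TO_CM1

#: Most-abundant-isotope masses in amu, used unless the caller overrides.
ISOTOPE_MASSES_AMU = {
    "H": 1.00782503207,
    "D": 2.01410177785,
    "He": 4.00260325413,
    "Li": 7.016003437,
    "B": 11.009305167,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "F": 18.99840316273,
    "Ne": 19.9924401762,
    "Na": 22.989769282,
    "P": 30.97376199842,
    "S": 31.9720711744,
    "Cl": 34.968852682,
    "Ar": 39.9623831237,
    "Br": 78.9183376,
    "I": 126.9044719,
}


def mass_of(element: str) -> float:
    """Mass of ``element`` in electron masses (most-abundant isotope)."""
    try:
        return ISOTOPE_MASSES_AMU[element] * AMU_TO_ME
    except KeyError:
        raise KeyError(
            f"no tabulated mass for element {element!r}; supply masses explicitly"
        ) from None
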