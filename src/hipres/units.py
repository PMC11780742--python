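"""Physical constants and unit conversions.

All internal math is in Hartree atomic units (bohr, hartree). File I/O and the
CLI speak Å and GPa. Conversion factors are fixed here so that results are
bit-reproducible across environments.
"""

# 1 Å in bohr
BOHR_PER_ANGSTROM = 1.8897261246
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

# 1 hartree/bohr^3 in GPa
GPA_PER_AU_PRESSURE = 29421.0265
AU_PRESSURE_PER_GPA = 1.0 / GPA_PER_AU_PRESSURE

# 1 hartree in kJ/mol
KJMOL_PER_HARTREE = 2625.4996

# Bondi van der Waals radii, Å. Used as cavity sphere radii unless overridden.
BONDI_RADII_ANGSTROM = {
    "H": 1.20,
    "He": 1.40,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Ne": 1.54,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Ar": 1.88,
}

ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}
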