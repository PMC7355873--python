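"""Physical constants and unit conversions.

Internal unit system is atomic units with hbar = 1: lengths in bohr,
energies in hartree, masses in electron masses.  User-facing masses are in
amu, lengths reported in Angstrom (or mAA / uAA), frequencies in cm^-1 and
shieldings in ppm (shifts in ppb).
"""

# CODATA 2018
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

#: electron masses per unified atomic mass unit
AMU_TO_ME = 1822.888486209

#: hartree (angular frequency in a.u.) expressed in wavenumbers
HARTREE_TO_INVCM = 219474.6313632

#: parts-per-million -> parts-per-billion
PPM_TO_PPB = 1000.0

# isotope masses (amu) used by the fixtures
MASS_H1 = 1.007825
MASS_H2 = 2.014102
MASS_C12 = 12.000000
MASS_C13 = 13.003355
MASS_O16 = 15.994915
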