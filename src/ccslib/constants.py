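"""Versioned physical-constant tables.

Atomic masses and isotopic abundances are pinned here (IUPAC/NIST 2021
standard values) rather than fetched at runtime, so that every mass the
package reports is reproducible from the repository alone.

``MONOISOTOPIC_MASS`` holds the mass of the most abundant isotope of each
element in Da.  ``M1_ABUNDANCE_RATIO`` holds, for elements possessing a
one-neutron-heavier isotope (13C, 2H, 15N, 17O, 33S, ...), the natural
minor/major abundance ratio used by the linear (M+1)/M approximation.
Elements whose first heavy isotope is two neutrons up (Cl, Br) contribute
at M+2, not M+1, and are listed with ratio 0.
"""

from __future__ import annotations

# Da, most abundant isotope (12C defines the scale)
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "Li": 7.0160034366,
    "B": 11.00930536,
    "C": 12.0,
    "N": 14.0030740044,
    "O": 15.9949146196,
    "F": 18.9984031627,
    "Na": 22.9897692820,
    "Mg": 23.985041697,
    "Al": 26.98153853,
    "Si": 27.9769265347,
    "P": 30.9737619984,
    "S": 31.9720711744,
    "Cl": 34.9688527,
    "K": 38.9637064864,
    "Ca": 39.962590863,
    "Ti": 47.94794198,
    "Cr": 51.94050623,
    "Mn": 54.93804391,
    "Fe": 55.93493633,
    "Ni": 57.93534241,
    "Cu": 62.92959772,
    "Zn": 63.92914201,
    "As": 74.92159457,
    "Se": 79.9165218,
    "Br": 78.9183376,
    "Sr": 87.9056125,
    "Mo": 97.90540482,
    "Ag": 106.9050916,
    "Cd": 113.90336509,
    "Sn": 119.90220163,
    "Sb": 120.903812,
    "I": 126.9044719,
    "Ba": 137.905247,
    "Hg": 201.9706434,
    "Pb": 207.9766525,
}

# minor/major natural-abundance ratio for the one-neutron-heavier isotope
M1_ABUNDANCE_RATIO: dict[str, float] = {
    "H": 0.000115 / 0.999885,       # 2H / 1H
    "C": 0.0107 / 0.9893,           # 13C / 12C
    "N": 0.00364 / 0.99636,         # 15N / 14N
    "O": 0.00038 / 0.99757,         # 17O / 16O
    "S": 0.0075 / 0.9499,           # 33S / 32S
    "Si": 0.04685 / 0.92223,        # 29Si / 28Si
}

# Da; charge carriers for singly charged adducts
PROTON_MASS = 1.00727646688
ELECTRON_MASS = 0.00054857990
SODIUM_CATION_MASS = MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS  # 22.98922070

# CODATA 2018
ELEMENTARY_CHARGE = 1.602176634e-19      # C
BOLTZMANN = 1.380649e-23                 # J/K
ATOMIC_MASS_UNIT = 1.66053906660e-27     # kg
# gas number density at 273.15 K, 101325 Pa (Loschmidt constant), m^-3
LOSCHMIDT = 101325.0 / (BOLTZMANN * 273.15)

# Da, monoisotopic mass of N2 buffer gas
NITROGEN_GAS_MASS = 2 * MONOISOTOPIC_MASS["N"]
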