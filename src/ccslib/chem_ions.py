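"""Molecular-formula arithmetic for singly charged adduct ions.

Parses Hill-style molecular formulas, computes monoisotopic masses, adduct
m/z values for the four ion types observed in the library workflow
([M+H]+, [M+Na]+, [M-H]-, [M+]+.), the expected first-isotopologue
(M+1)/M intensity ratio, and ppm mass errors.

Only |z| = 1 species are modelled.  The (M+1)/M ratio uses the linear
one-neutron approximation (sum over elements of count x minor/major
abundance), which is adequate for molecules below ~1 kDa; full
isotopologue convolution is deliberately out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .constants import (
    ELECTRON_MASS,
    M1_ABUNDANCE_RATIO,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    SODIUM_CATION_MASS,
)

__all__ = [
    "ElementCounts",
    "IonType",
    "ION_TYPES",
    "MODE_ION_TYPES",
    "TheoreticalIon",
    "parse_formula",
    "hill_formula",
    "monoisotopic_mass",
    "ion_mz",
    "m1_ratio",
    "ppm_error",
    "theoretical_ion",
]

#: element symbol -> count; values are strictly positive
ElementCounts = dict[str, int]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)")


@dataclass(frozen=True)
class IonType:
    """A singly charged adduct: label, charge sign and constant mass shift.

    ``mass_shift`` is added to the neutral monoisotopic mass to obtain the
    ion m/z (|z| = 1 throughout): +proton for [M+H]+, +Na-minus-electron
    for [M+Na]+, -proton for [M-H]-, -electron for the radical cation.
    """

    label: str
    charge_sign: int
    mass_shift: float

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.label


ION_TYPES: dict[str, IonType] = {
    "[M+H]+": IonType("[M+H]+", +1, PROTON_MASS),
    "[M+Na]+": IonType("[M+Na]+", +1, SODIUM_CATION_MASS),
    "[M-H]-": IonType("[M-H]-", -1, -PROTON_MASS),
    "[M+]+": IonType("[M+]+", +1, -ELECTRON_MASS),
}

#: adducts evaluated per ionization mode: deprotonated in ESI-, protonated
#: and sodiated in ESI+, protonated and radical cation in APCI+
MODE_ION_TYPES: dict[str, tuple[str, ...]] = {
    "ESI-": ("[M-H]-",),
    "ESI+": ("[M+H]+", "[M+Na]+"),
    "APCI+": ("[M+H]+", "[M+]+"),
}

MODES: tuple[str, ...] = ("ESI+", "ESI-", "APCI+")


@dataclass(frozen=True)
class TheoreticalIon:
    """Expected ion for one neutral formula and adduct type."""

    formula: str
    ion_type: IonType
    mz: float
    m1_ratio: float


class FormulaError(ValueError):
    """Raised for unparseable or chemically invalid formula strings."""


def parse_formula(text: str) -> ElementCounts:
    """Parse a Hill-style molecular formula into element counts.

    Digits are optional (absent means 1); parenthesised groups with
    multipliers are accepted ("Ca(OH)2").  Charges and isotope labels are
    not part of a neutral formula and are rejected.

    Raises :class:`FormulaError` on empty input, unknown element symbols,
    or zero multipliers.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    stack: list[ElementCounts] = [{}]
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos:
            raise FormulaError(f"unparseable formula {text!r} at position {pos}")
        sym, num, open_p, close_p, group_num = m.groups()
        if open_p:
            stack.append({})
        elif close_p:
            if len(stack) == 1:
                raise FormulaError(f"unbalanced ')' in {text!r}")
            mult = int(group_num) if group_num else 1
            if mult == 0:
                raise FormulaError(f"zero group multiplier in {text!r}")
            group = stack.pop()
            for el, n in group.items():
                stack[-1][el] = stack[-1].get(el, 0) + n * mult
        else:
            if sym not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
            n = int(num) if num else 1
            if n == 0:
                raise FormulaError(f"zero count for {sym} in {text!r}")
            stack[-1][sym] = stack[-1].get(sym, 0) + n
        pos = m.end()
    if len(stack) != 1:
        raise FormulaError(f"unbalanced '(' in {text!r}")
    counts = stack[0]
    if not counts:
        raise FormulaError(f"formula {text!r} contains no elements")
    return counts


def hill_formula(counts: ElementCounts) -> str:
    """Canonical Hill-order string: C, H, then other elements alphabetically."""
    if not counts:
        raise FormulaError("empty element counts")
    order: list[str] = []
    if "C" in counts:
        order.append("C")
        if "H" in counts:
            order.append("H")
        order += sorted(el for el in counts if el not in ("C", "H"))
    else:
        order = sorted(counts)
    return "".join(
        f"{el}{counts[el]}" if counts[el] != 1 else el for el in order
    )


def monoisotopic_mass(counts: ElementCounts) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a neutral formula, Da."""
    mass = 0.0
    for el, n in counts.items():
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"no mass entry for element {el!r}")
        if n <= 0:
            raise FormulaError(f"non-positive count for {el!r}")
        mass += n * MONOISOTOPIC_MASS[el]
    if not counts:
        raise FormulaError("empty element counts")
    return mass


def ion_mz(counts: ElementCounts, ion_type: IonType | str) -> float:
    """m/z of a singly charged adduct: neutral mass plus the adduct shift."""
    if isinstance(ion_type, str):
        ion_type = ION_TYPES[ion_type]
    return monoisotopic_mass(counts) + ion_type.mass_shift


def m1_ratio(counts: ElementCounts) -> float:
    """Expected (M+1)/M intensity ratio, linear one-neutron approximation.

    Sums count x (minor/major abundance) over the elements with a
    one-neutron-heavier isotope (13C dominates for organics).
    """
    return sum(
        n * M1_ABUNDANCE_RATIO.get(el, 0.0) for el, n in counts.items()
    )


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error in parts per million; gates use the absolute value."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


def theoretical_ion(formula: ElementCounts | str, ion_type: IonType | str) -> TheoreticalIon:
    """Bundle the expected m/z and isotope ratio for one formula + adduct."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    if isinstance(ion_type, str):
        ion_type = ION_TYPES[ion_type]
    return TheoreticalIon(
        formula=hill_formula(counts),
        ion_type=ion_type,
        mz=ion_mz(counts, ion_type),
        m1_ratio=m1_ratio(counts),
    )
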