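"""Adduct m/z and isotope ratios from a molecular formula.

Thiabendazole (C10H7N3S), a benzimidazole fungicide, forms different ions
under electrospray and APCI: deprotonated in negative mode, protonated /
sodiated in positive mode, and a radical cation under APCI.  The expected
(M+1)/M ratio (~0.13 here, dominated by ten 13C chances) is what the
isotope gate checks a measured feature against.
"""

from ccslib import ION_TYPES, m1_ratio, monoisotopic_mass, parse_formula, ppm_error, theoretical_ion

formula = parse_formula("C10H7N3S")
print(f"thiabendazole  C10H7N3S  M = {monoisotopic_mass(formula):.6f} Da")
print(f"expected (M+1)/M ratio = {m1_ratio(formula):.4f}")
for label in ION_TYPES:
    theo = theoretical_ion(formula, label)
    print(f"  {label:9s} m/z = {theo.mz:10.6f}")

observed = 202.0450  # a measured feature near the protonated ion
theo = theoretical_ion(formula, "[M+H]+")
err = ppm_error(observed, theo.mz)
print(f"observed {observed} vs [M+H]+ -> {err:+.2f} ppm "
      f"({'inside' if abs(err) < 10 else 'outside'} the 10 ppm gate)")
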