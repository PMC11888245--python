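"""Suspect screening: matching a measured feature against the library.

A query (m/z, CCS) matches library entries inside a 10 ppm mass window and
2% CCS window; hits are ranked by a normalised quadratic score (0 = perfect
match).  Offsetting the query by +5 ppm / +0.5% CCS still matches; +3% CCS
does not, even at the exact m/z.
"""

from ccslib import QueryFeature, suspect_screen
from ccslib.pipeline import curate
from ccslib.synthetic import SimConfig, simulate_campaign

registry, truth, features, manifest, cal = simulate_campaign(SimConfig(n_chemicals=500, seed=7))
library = curate(registry, features, cal).entries
target = library[0]
print(f"target entry: {target.chem_id} {target.ion_type} {target.mode} "
      f"m/z {target.mz:.4f}, CCS {target.ccs:.2f} A^2")

for label, dppm, dccs in [("exact", 0.0, 0.0), ("+5 ppm, +0.5% CCS", 5e-6, 0.005),
                          ("+3% CCS", 0.0, 0.03)]:
    q = QueryFeature("q", target.mode, target.mz * (1 + dppm), target.ccs * (1 + dccs))
    hits = suspect_screen(q, library)
    if hits:
        print(f"{label:20s} -> rank-1 {hits[0].chem_id} "
              f"(ppm {hits[0].ppm:+.2f}, dCCS {hits[0].delta_ccs_pct:+.2f}%, "
              f"score {hits[0].score:.3f})")
    else:
        print(f"{label:20s} -> no hit (outside the CCS window)")
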