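# ccslib

Build, curate and screen **drift-tube ion mobility–mass spectrometry (DTIMS-MS)
collision cross section (CCS) libraries**.

Reference CCS libraries let non-targeted and suspect-screening studies of
environmental contaminants (pesticides, PFAS, PAHs, pharmaceuticals, ...)
identify features by two orthogonal physical properties — m/z and CCS —
without running a standard for every chemical in every sample. `ccslib` is
aimed at analytical chemists and exposomics researchers who need to turn
replicate drift-tube measurements of chemical standards into a curated
library, and then use that library for screening and cross-laboratory
comparison.

## What it computes

**Formula/ion arithmetic.** Hill-formula parsing, monoisotopic masses from a
versioned IUPAC constants table, adduct m/z for the four singly charged ion
types ([M+H]⁺, [M+Na]⁺, [M−H]⁻, [M+]⁺˙) and the expected (M+1)/M isotope
ratio (linear one-neutron approximation; ¹³C dominated).

**Drift-tube physics.** The Mason–Schamp relation between reduced mobility
and CCS,

    Ω = (3 z e) / (16 N₀) · √(2π / (μ k_B T)) · 1 / K₀ ,

and the **single-field calibration** used in practice: calibrant (tune-mix)
ions with accepted reference CCS define the line

    t_A = β · (√μ / z) · Ω + t_fix ,

whose slope β and dead time t_fix then convert unknown arrival times to CCS
(`fit_single_field`, `drift_to_ccs`, `ccs_to_drift`).

**QC curation.** An ion counts as detected only if its mass error is inside
a strict 10 ppm window *and* its isotope ratio matches the formula; a CCS is
kept only if two replicates agree within 1 % (percent difference on the
pair mean); entries further than 15 % from the power-law CCS–m/z trendline
of their ion type are removed — this catches multimer "streaking", where
solution-phase multimers drift as multimers but appear at monomer m/z with
anomalously large CCS. Survivors become the library; a conservation report
accounts for every candidate in exactly one stage bucket.

**Screening and statistics.** Suspect screening inside 10 ppm / 2 % windows
with a normalised quadratic rank score; inter-library comparison binned at
the community's 2 % / 5 % thresholds; detection frequencies per chemical
class and ionization mode (ESI+/ESI−/APCI+) with three-mode Venn overlap;
Fisher's exact test for detection-vs-stability/amenability associations.

**Synthetic campaigns.** `ccslib.synthetic` generates registries with
class-structured formulas (PFAS carry fluorine, PAHs are CₓHᵧ), mode- and
class-dependent detectability, power-law CCS truth with realistic scatter,
duplicate-injection noise and multimer artifacts — so the full pipeline is
testable end to end without instrument data.

## Worked example

`examples/03_synthetic_campaign_curation.py` simulates a 500-chemical
campaign (duplicate injections, 2 % multimer rate at +40 % CCS) and curates
it:

```
simulated 500 chemicals -> 346 true ions, 692 replicate rows, 9 multimer artifacts
  n_candidates         346
  rejected_ppm         0
  rejected_isotope     0
  rejected_replicate   12
  rejected_trendline   9
  retained             325
counts conserved: True
artifacts surviving into the library: 0 (trendline filter removes the +40% CCS streaks)
final library: 325 (chemical, adduct, mode) entries
```

346 candidate ions enter; 12 fail the 1 % replicate-agreement gate (the
expected few-percent attrition at 0.3–0.4 % replicate CV), and the
trendline filter removes exactly the 9 injected multimer artifacts — none
survive into the library. The other examples cover formula/adduct math,
calibration, screening (a query offset +5 ppm / +0.5 % CCS still matches;
+3 % CCS does not) and comparison statistics.

A thin CLI mirrors the stages:

```bash
ccslib simulate --seed 7 --n-chemicals 500 --out-dir demo
ccslib curate --registry demo/registry.csv --features demo/features.csv \
              --calibrants demo/calibrants.csv --out-dir demo
ccslib summarize demo/registry.csv demo/library.tsv --out demo/summary.json
```

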