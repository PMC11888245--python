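# Methods

## Scope and model

`ccslib` implements the data-analysis half of a drift-tube IMS-MS (DTIMS)
reference-library campaign: everything after peaks have been picked from
the raw instrument files. The package assumes singly charged ions
(|z| = 1), nitrogen buffer gas, and the four adducts routinely evaluated
for small-molecule screening — [M−H]⁻ in ESI−, [M+H]⁺ and [M+Na]⁺ in ESI+,
[M+H]⁺ and [M+]⁺˙ in APCI+. Multiply charged species, in-source fragments
and fine isotope structure are out of scope.

## Formula and isotope arithmetic

Formulas are parsed from Hill-style strings (optional parenthesised
groups); monoisotopic masses come from a constants table pinned in the
repository (IUPAC/NIST standard values; ¹²C = 12 exactly) rather than any
runtime lookup, so results are reproducible from the source tree alone.
Adduct m/z adds a constant shift per ion type: +1.00727647 Da (proton),
+22.98922070 Da (sodium cation), −1.00727647 Da, −0.00054858 Da (electron).

The expected (M+1)/M intensity ratio uses the linear one-neutron
approximation: the sum over elements of count × (minor/major abundance)
for one-neutron-heavier isotopes (¹³C, ²H, ¹⁵N, ¹⁷O, ³³S, ²⁹Si). For the
M+1 isotopologue this sum is in fact the exact hypergeometric expectation;
what the approximation ignores is contributions beyond one neutron, which
is adequate below ~1 kDa. Chlorine and bromine contribute at M+2 and are
deliberately absent from the M+1 table.

## Drift-tube physics and calibration

`mobility_to_ccs` evaluates the Mason–Schamp equation with CODATA 2018
constants and the buffer-gas number density at standard conditions
(273.15 K, 101325 Pa). Units are fixed package-wide: time in ms, CCS in Å²,
mass in Da, reduced mobility in cm² V⁻¹ s⁻¹.

The single-field calibration is an ordinary (unweighted) least-squares fit
of calibrant arrival time against γ·Ω_ref with γ = √μ/z, giving slope β
(ms per Å²·√Da) and dead-time intercept t_fix (ms). Because this transfers
*reference* CCS values rather than absolute physics, calibrated CCS does
not depend directly on the drift-gas temperature; the `DriftConditions`
default of 298.15 K matters only for the direct Mason–Schamp route and is
configurable. Default cell geometry follows a typical commercial drift
tube (78.24 cm, ~3.95 torr N₂, 17 V/cm). Tune-mix reference CCS values are
always an *input table*, never hard-coded truth; the representative table
in `ccslib.synthetic.DEFAULT_TUNE_MIX` is a synthetic fixture shaped like
the published vendor tune-mix scale.

## QC gates

- **Detection gate.** A replicate feature matches an expected adduct when
  |ppm| < 10 — strict, so exactly 10.000 ppm fails — *and* its observed
  (M+1)/M ratio is within 30 % relative error of the formula expectation.
  The mass tolerance is the community convention; the isotope tolerance is
  a package choice (the qualitative criterion "correct ¹³C distribution"
  has no standard numeric form) and is configurable. Replicate rows are
  assigned to the nearest expected adduct m/z of their mode; the adducts
  evaluated per mode are 22 Da apart or more, so assignment is
  unambiguous at ppm scales.
- **Replicate gate.** Percent difference on the pair mean,
  100·|a−b|/((a+b)/2), must be ≤ 1 % for at least one pair of replicates;
  with more than two replicates the reported CCS is the mean of the
  largest mutually agreeing subset. A single replicate cannot confirm
  reproducibility and fails.
- **Trendline filter.** CCS grows as a power law of m/z within an ion
  type; `fit_trendline` fits log CCS against log m/z by least squares, per
  ion type when ≥ 20 points are available (global fallback otherwise —
  which trendline scope is "correct" is genuinely open; per-ion-type is
  the physically finer choice). Entries with residuals beyond 15 % of the
  predicted CCS are rejected. The fit is single-pass (fit once, filter
  once); an iterative robust refit was considered and left out because at
  the artifact contamination levels modelled (~2 % at +40 %) the log-space
  OLS slope moves by < 0.01, which does not change any filtering decision.
- **Assembly.** Retained candidates become one library entry per
  (chemical, adduct, mode), CCS reported as the arithmetic mean of the
  agreeing replicates to 2 decimal places. Duplicated registry identifiers
  collapse to one chemical. The curation report is conserved by
  construction: every candidate lands in exactly one of
  {retained, rejected ppm, rejected isotope, rejected replicate,
  rejected trendline}.

## Screening and comparison

Suspect screening accepts hits inside 10 ppm and (when the query carries a
CCS) 2 % windows and ranks by score = (|ppm|/tol)² + (|ΔCCS%|/tol)² — a
normalised quadratic chosen because it is invariant to the tolerance
scales; there is no community-standard ranking rule. Inter-library
comparison joins on (chem_id, ion_type) by default, falling back to
(formula, ion_type) for libraries without shared identifiers, and bins the
pair-mean percent differences at ≤ 2 %, (2 %, 5 %] and > 5 % — the
accepted instrument-variability and method-difference thresholds. The
pair-mean denominator makes the comparison symmetric in the two libraries.

## Statistics

Fisher's exact test (two-sided, point-probability rule) is delegated to
`scipy.stats.fisher_exact`; the test suite verifies it against a
from-scratch integer-arithmetic hypergeometric enumeration over every 2×2
table with total ≤ 40. Cross-tab fractions are computed in exact rational
arithmetic before conversion to float, so they sum to 1 identically;
chemicals with a missing flag are excluded listwise. For amenability flags
"detected" means detected in the corresponding ESI mode; for stability it
means detected in any mode.

## Synthetic campaign generator

The generator emulates the statistical structure the pipeline assumes,
with defaults chosen to mirror a realistic screening campaign:

- **Registry.** 13 use/source classes with weights proportional to a
  regulatory screening-library composition; class-conditioned formula
  caricatures (PAHs pure CₓHᵧ from ring counts, PFAS perfluorinated
  carboxylic acids, surfactants long-chain C₁₀–C₁₈ with oxygens and
  optional sulfur, otherwise generic CHNOS(Cl)).
- **Detectability.** Per-class per-mode Bernoulli detection with
  probabilities set so that (i) PAHs are found almost only by APCI+, PFAS
  almost only by ESI−, (ii) per-class detectability spans roughly 20–70 %,
  and (iii) the marginal fraction of chemicals detected in at least one
  mode is ≈ 45–46 % — the regime a broad xenobiotic campaign operates in.
- **CCS truth.** ccs = a·mz^b per ion type (defaults a ≈ 10, b = 0.5,
  ≈ 141 Å² at m/z 200) with 3 % Gaussian relative scatter. The scatter
  draw is shared across modes for the same adduct of the same chemical —
  one physical ion has one CCS regardless of source.
- **Noise.** Two replicates per ion; CCS noise CV 0.3 % (ESI) and 0.42 %
  (APCI), values at which the closed form
  P(pass 1 % gate) = 2Φ(1/(CV·√2)) − 1 gives ≈ 98 % and ≈ 91 % duplicate
  agreement — the reproducibility regime of the two source types. m/z
  noise 2 ppm; isotope-ratio noise 10 % relative.
- **Artifacts.** With probability 2 % an ion streaks as a multimer: its
  replicate CCS values are inflated by +40 % while m/z stays at the
  monomer value, and the manifest records the key. The inflation is
  applied to the whole ion (both replicates) because the physical artifact
  affects the drift population, not individual injections; this also makes
  the recovery criterion exact — at 3 % scatter vs a 15 % tolerance the
  artifact and genuine populations are fully separable, so the
  trendline-rejected set equals the manifest restricted to QC survivors.
- **Flags.** Stability is drawn from a logistic model with baseline
  P(stable) = 0.40 and detection log-odds coefficient ln 3 (odds ratio 3),
  with 22 % of flags missing; ESI amenability likewise (baseline 0.30,
  odds ratio 4). Detection indicators are drawn from a dedicated named
  substream so the registry flags and the truth table stay mutually
  consistent while each generator function remains independently callable.

Everything is a deterministic function of (config, seed) via named
`SeedSequence` substreams.

**What the generator does not model** — and therefore what passing tests
do not establish about real data: ionization physics and matrix effects
(detectability is an exogenous Bernoulli, not a function of structure),
chromatographic or peak-shape effects, carryover, saturation, isomer
interference, correlated drift of the calibration within a worklist, and
real CCS fine structure beyond a single power law per ion type with
independent scatter. Conclusions about gate behaviour transfer to real
campaigns only to the extent that replicate noise is approximately
Gaussian and artifacts are large relative to trendline scatter.

## Problem sizes and numerical choices

The reference validation campaign uses 2,000 chemicals (seed 7), chosen to
keep every per-mode pair count in the hundreds-to-thousands range where
the Monte-Carlo comparisons (2-point tolerance) are stable. Law-of-large-
numbers checks on the generator use n = 10,000. The Fisher cross-check
enumerates all 135,750 tables with total ≤ 40 exactly. Round-trip and
oracle equivalences are asserted at 1e-9 relative (drift↔CCS) and six
significant figures (Mason–Schamp); the agreement observed is at machine
precision. Degenerate inputs fail loudly: empty formulas, non-positive
masses or tolerances, arrival times at or below the dead time, all-equal
calibrant abscissae, all-zero contingency tables and unjoinable library
pairs all raise with specific messages.

## Known limitations

- The (M+1)/M gate uses one relative tolerance for all masses; at very low
  expected ratios (few carbons) the absolute ratio difference is tiny and
  the gate is effectively loose.
- The trendline filter assumes one dominant power law per ion type; highly
  halogenated classes in a real campaign can sit on secondary trendlines,
  and a 15 % band around a single fit may clip them.
- Percent-difference subsetting with > 2 replicates enumerates subsets and
  is exponential in replicate count; it is intended for the 2–6 replicate
  regime of practical campaigns.
- The CLI holds whole tables in memory; libraries of 10⁵+ entries are
  better driven through the API.
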