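"""Synthetic IMS-MS campaign generator.

Emulates the statistical structure of a drift-tube CCS library campaign so
that every pipeline stage is testable without instrument data:

- a chemical registry with class-structured formulas (PFAS carry fluorine,
  PAHs are pure CxHy, ...) and class weights following a realistic
  screening-library composition;
- class- and mode-dependent detectability across ESI+/ESI-/APCI+;
- a power-law CCS-m/z trend per ion type with a few percent natural
  scatter;
- duplicate injections with ~0.3% replicate CCS noise;
- multimer "streaking" artifacts: with small probability an ion's measured
  CCS is inflated (default +40%) at the monomer m/z, the signature of
  solution-phase multimers breaking up after the drift cell;
- stability and ESI-amenability flags whose odds are correlated with
  detection.

All outputs are a deterministic function of (config, seed); independent
named substreams keep the registry, truth and noise draws reproducible
across partial re-runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ccs_core import CalibrantIon, SingleFieldCalibration, ccs_to_drift, fit_single_field
from .chem_ions import (
    ION_TYPES,
    MODE_ION_TYPES,
    MODES,
    ElementCounts,
    hill_formula,
    ion_mz,
    m1_ratio,
)
from .curation import ChemicalRecord

__all__ = [
    "SimConfig",
    "TruthIon",
    "DEFAULT_TUNE_MIX",
    "generate_registry",
    "simulate_truth",
    "simulate_runs",
    "generate_tune_mix",
    "simulate_campaign",
]

#: 13 broad use/source classes with weights proportional to a realistic
#: regulatory screening-library composition
TOXCAST_CLASS_WEIGHTS: dict[str, float] = {
    "Natural Toxin": 6,
    "Disinfection By-Product": 14,
    "PFAS": 17,
    "PAH": 31,
    "Surfactant": 78,
    "Flame Retardant": 120,
    "Plastic": 154,
    "Color Dye": 172,
    "Cosmetic Ingredient": 360,
    "Pharmaceutical": 615,
    "Food Additive": 634,
    "Pesticide": 948,
    "Chemical Industrial": 1536,
}

#: per-class detection probability per ionization mode; PAHs ionize mainly
#: by APCI+, PFAS by ESI-, most classes favour ESI
DEFAULT_DETECTION_PROBS: dict[str, dict[str, float]] = {
    "Natural Toxin": {"ESI+": 0.28, "ESI-": 0.21, "APCI+": 0.11},
    "Disinfection By-Product": {"ESI+": 0.14, "ESI-": 0.25, "APCI+": 0.11},
    "PFAS": {"ESI+": 0.04, "ESI-": 0.46, "APCI+": 0.04},
    "PAH": {"ESI+": 0.04, "ESI-": 0.01, "APCI+": 0.43},
    "Surfactant": {"ESI+": 0.25, "ESI-": 0.32, "APCI+": 0.07},
    "Flame Retardant": {"ESI+": 0.21, "ESI-": 0.18, "APCI+": 0.21},
    "Plastic": {"ESI+": 0.21, "ESI-": 0.18, "APCI+": 0.18},
    "Color Dye": {"ESI+": 0.39, "ESI-": 0.35, "APCI+": 0.18},
    "Cosmetic Ingredient": {"ESI+": 0.25, "ESI-": 0.21, "APCI+": 0.14},
    "Pharmaceutical": {"ESI+": 0.39, "ESI-": 0.28, "APCI+": 0.21},
    "Food Additive": {"ESI+": 0.09, "ESI-": 0.07, "APCI+": 0.04},
    "Pesticide": {"ESI+": 0.25, "ESI-": 0.21, "APCI+": 0.14},
    "Chemical Industrial": {"ESI+": 0.21, "ESI-": 0.18, "APCI+": 0.11},
}

#: power-law CCS-m/z truth per ion type (a, b): ccs = a * mz**b; ~141 A^2
#: at m/z 200 for b = 0.5, a = 10 — typical small-molecule territory
DEFAULT_TRENDLINES: dict[str, tuple[float, float]] = {
    "[M+H]+": (10.0, 0.50),
    "[M+Na]+": (10.2, 0.50),
    "[M-H]-": (9.8, 0.50),
    "[M+]+": (10.0, 0.50),
}

#: representative singly charged tune-mix-style calibrant ions
#: (m/z, reference CCS in A^2).  SYNTHETIC fixture values, shaped like the
#: published vendor tune-mix scale; not measurement data.
DEFAULT_TUNE_MIX: tuple[tuple[float, float], ...] = (
    (118.0863, 121.30),
    (322.0481, 153.73),
    (622.0290, 202.96),
    (922.0098, 243.64),
    (1221.9906, 282.20),
    (1521.9715, 316.96),
)


@dataclass(frozen=True)
class SimConfig:
    """Campaign-level simulation settings.

    ``replicate_cv_pct`` defaults to 0.3 so that the overwhelming majority
    of duplicate injections agree within the 1% reproducibility gate;
    ``apci_replicate_cv_pct`` is larger, reflecting the less reproducible
    APCI source.  ``multimer_rate``/``multimer_inflation_pct`` control the
    streaking-artifact channel.
    """

    n_chemicals: int = 2000
    seed: int = 0
    class_weights: dict[str, float] = field(
        default_factory=lambda: dict(TOXCAST_CLASS_WEIGHTS)
    )
    detection_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_DETECTION_PROBS.items()
        }
    )
    trendline_truth: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRENDLINES)
    )
    trendline_scatter_pct: float = 3.0
    replicate_cv_pct: float = 0.3
    apci_replicate_cv_pct: float = 0.42
    n_replicates: int = 2
    multimer_rate: float = 0.02
    multimer_inflation_pct: float = 40.0
    mz_noise_ppm: float = 2.0
    m1_noise_rel: float = 0.10
    # P(stable) follows logit(p) = logit(baseline) + log_odds * detected
    stability_baseline: float = 0.40
    stability_detect_log_odds: float = math.log(3.0)
    stability_missing_rate: float = 0.22
    amenability_baseline: float = 0.30
    amenability_detect_log_odds: float = math.log(4.0)
    # single-field calibration truth
    cal_beta: float = 0.21
    cal_t_fix: float = 0.20

    def __post_init__(self) -> None:
        if self.n_chemicals < 1:
            raise ValueError("n_chemicals must be >= 1")
        if not (0 <= self.multimer_rate <= 1):
            raise ValueError("multimer_rate must be in [0, 1]")
        for cls, per_mode in self.detection_probs.items():
            for mode, p in per_mode.items():
                if not (0 <= p <= 1):
                    raise ValueError(f"detection prob out of range for {cls}/{mode}")
        if any(w < 0 for w in self.class_weights.values()):
            raise ValueError("class weights must be non-negative")


@dataclass(frozen=True)
class TruthIon:
    """Ground truth for one detectable adduct ion."""

    chem_id: str
    formula: str
    chem_class: str
    ion_type: str
    mode: str
    mz: float
    ccs: float
    m1_ratio: float


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


_STREAM_CLASSES = 0
_STREAM_FORMULAS = 1
_STREAM_DETECT = 2
_STREAM_FLAGS = 3
_STREAM_TRUTH = 4
_STREAM_RUNS = 5
_STREAM_TUNEMIX = 6


def _sample_formula(chem_class: str, rng: np.random.Generator) -> ElementCounts:
    """Class-conditioned element counts (caricatures of real structures)."""
    if chem_class == "PAH":
        rings = int(rng.integers(2, 8))
        return {"C": 4 * rings + 2, "H": 2 * rings + 4}
    if chem_class == "PFAS":
        n = int(rng.integers(4, 13))  # perfluorinated carboxylic acids
        return {"C": n + 1, "H": 1, "F": 2 * n + 1, "O": 2}
    if chem_class == "Surfactant":
        c = int(rng.integers(10, 19))
        counts: ElementCounts = {"C": c, "H": 2 * c + 2, "O": int(rng.integers(2, 7))}
        if rng.random() < 0.5:
            counts["S"] = 1
        return counts
    c = int(rng.integers(6, 31))
    counts = {"C": c, "H": max(1, int(c * rng.uniform(1.0, 2.1)))}
    n = int(rng.integers(0, 5))
    o = int(rng.integers(0, 9))
    if n:
        counts["N"] = n
    if o:
        counts["O"] = o
    if rng.random() < 0.2:
        counts["S"] = 1
    cl = int(rng.poisson(0.3))
    if cl:
        counts["Cl"] = min(cl, 4)
    return counts


def _detection_matrix(cfg: SimConfig, classes: Sequence[str]) -> np.ndarray:
    """Boolean (n_chemicals x 3 modes) detection indicators; drawn from a
    dedicated substream so registry flags and truth stay consistent."""
    rng = _rng(cfg, _STREAM_DETECT)
    u = rng.random((len(classes), len(MODES)))
    probs = np.array(
        [
            [cfg.detection_probs.get(cls, {}).get(m, 0.0) for m in MODES]
            for cls in classes
        ]
    )
    return u < probs


def _sampled_classes(cfg: SimConfig) -> list[str]:
    rng = _rng(cfg, _STREAM_CLASSES)
    labels = list(cfg.class_weights)
    w = np.array([cfg.class_weights[c] for c in labels], dtype=float)
    if w.sum() <= 0:
        raise ValueError("class weights sum to zero")
    return list(rng.choice(labels, size=cfg.n_chemicals, p=w / w.sum()))


def generate_registry(cfg: SimConfig) -> list[ChemicalRecord]:
    """Sample a chemical registry: formulas, classes, stability and
    amenability flags (flag odds correlated with detectability)."""
    classes = _sampled_classes(cfg)
    f_rng = _rng(cfg, _STREAM_FORMULAS)
    flag_rng = _rng(cfg, _STREAM_FLAGS)
    detect = _detection_matrix(cfg, classes)
    detected_any = detect.any(axis=1)
    mode_index = {m: i for i, m in enumerate(MODES)}

    base_logit = math.log(cfg.stability_baseline / (1 - cfg.stability_baseline))
    amen_logit = math.log(cfg.amenability_baseline / (1 - cfg.amenability_baseline))

    registry: list[ChemicalRecord] = []
    for i in range(cfg.n_chemicals):
        formula = _sample_formula(classes[i], f_rng)
        stable: bool | None
        if flag_rng.random() < cfg.stability_missing_rate:
            stable = None
        else:
            logit = base_logit + cfg.stability_detect_log_odds * detected_any[i]
            stable = bool(flag_rng.random() < 1 / (1 + math.exp(-logit)))
        amen: dict[str, bool] = {}
        for mode in ("ESI-", "ESI+"):
            logit = amen_logit + cfg.amenability_detect_log_odds * bool(
                detect[i, mode_index[mode]]
            )
            amen[mode] = bool(flag_rng.random() < 1 / (1 + math.exp(-logit)))
        registry.append(
            ChemicalRecord(
                chem_id=f"SYN{i:06d}",
                name=f"synthetic-{classes[i].lower().replace(' ', '-')}-{i}",
                formula=formula,
                chem_class=classes[i],
                stable=stable,
                amenable_esi_neg=amen["ESI-"],
                amenable_esi_pos=amen["ESI+"],
            )
        )
    return registry


#: probability that a detected chemical yields each adduct within a mode
#: (at least one is always emitted)
_ADDUCT_PROBS: dict[str, dict[str, float]] = {
    "ESI+": {"[M+H]+": 0.85, "[M+Na]+": 0.50},
    "ESI-": {"[M-H]-": 1.0},
    "APCI+": {"[M+H]+": 0.90, "[M+]+": 0.15},
}


def simulate_truth(registry: Sequence[ChemicalRecord], cfg: SimConfig) -> list[TruthIon]:
    """Draw the ground-truth library: which adduct ions exist per chemical
    and mode, with true m/z from the formula and true CCS on the ion-type
    power-law trendline plus lognormal-free relative scatter."""
    classes = [rec.chem_class for rec in registry]
    detect = _detection_matrix(cfg, classes)
    rng = _rng(cfg, _STREAM_TRUTH)
    truth: list[TruthIon] = []
    for i, rec in enumerate(registry):
        ratio = m1_ratio(rec.formula)
        # one physical CCS per adduct ion, shared across ionization modes
        eps_by_label: dict[str, float] = {}
        for j, mode in enumerate(MODES):
            if not detect[i, j]:
                continue
            adducts = []
            for label in MODE_ION_TYPES[mode]:
                if rng.random() < _ADDUCT_PROBS[mode][label]:
                    adducts.append(label)
            if not adducts:
                adducts = [MODE_ION_TYPES[mode][0]]
            for label in adducts:
                mz = ion_mz(rec.formula, ION_TYPES[label])
                a, b = cfg.trendline_truth[label]
                if label not in eps_by_label:
                    eps_by_label[label] = rng.normal(
                        0.0, cfg.trendline_scatter_pct / 100.0
                    )
                eps = eps_by_label[label]
                truth.append(
                    TruthIon(
                        chem_id=rec.chem_id,
                        formula=hill_formula(rec.formula),
                        chem_class=rec.chem_class,
                        ion_type=label,
                        mode=mode,
                        mz=mz,
                        ccs=a * mz**b * (1.0 + eps),
                        m1_ratio=ratio,
                    )
                )
    return truth


def simulate_runs(
    truth: Sequence[TruthIon],
    cal: SingleFieldCalibration,
    cfg: SimConfig,
) -> tuple[pd.DataFrame, list[dict]]:
    """Simulate replicate injections of every truth ion.

    Per ion, ``n_replicates`` rows with CCS noise (CV ``replicate_cv_pct``;
    the APCI-specific CV applies in APCI+ mode), arrival times from the
    forward single-field model, ~2 ppm m/z noise and ~10% relative isotope
    -ratio noise.  With probability ``multimer_rate`` the ion streaks as a
    multimer: all its replicate CCS values are inflated by
    ``multimer_inflation_pct`` while m/z stays at the monomer value.  The
    manifest lists the affected (chem_id, ion_type, mode) keys.
    """
    rng = _rng(cfg, _STREAM_RUNS)
    rows: list[dict] = []
    manifest: list[dict] = []
    for ion in truth:
        ccs_eff = ion.ccs
        if rng.random() < cfg.multimer_rate:
            ccs_eff = ion.ccs * (1.0 + cfg.multimer_inflation_pct / 100.0)
            manifest.append(
                {"chem_id": ion.chem_id, "ion_type": ion.ion_type, "mode": ion.mode}
            )
        cv = (
            cfg.apci_replicate_cv_pct
            if ion.mode == "APCI+"
            else cfg.replicate_cv_pct
        ) / 100.0
        for r in range(1, cfg.n_replicates + 1):
            ccs_obs = ccs_eff * (1.0 + rng.normal(0.0, cv)) if cv > 0 else ccs_eff
            mz_obs = ion.mz * (1.0 + rng.normal(0.0, cfg.mz_noise_ppm * 1e-6))
            m1_obs = ion.m1_ratio * (1.0 + rng.normal(0.0, cfg.m1_noise_rel))
            rows.append(
                {
                    "chem_id": ion.chem_id,
                    "mode": ion.mode,
                    "replicate_index": r,
                    "observed_mz": mz_obs,
                    "observed_m1_ratio": max(m1_obs, 0.0),
                    "t_A_ms": ccs_to_drift(ccs_obs, mz_obs, 1, cal),
                }
            )
    columns = [
        "chem_id",
        "mode",
        "replicate_index",
        "observed_mz",
        "observed_m1_ratio",
        "t_A_ms",
    ]
    return pd.DataFrame(rows, columns=columns), manifest


def generate_tune_mix(
    cal_truth: tuple[float, float],
    reference_ions: Sequence[tuple[float, float]] = DEFAULT_TUNE_MIX,
    noise_ms: float = 0.0,
    seed: int = 0,
) -> list[CalibrantIon]:
    """Arrival times for calibrant ions from the forward single-field model
    (beta, t_fix) = ``cal_truth``, plus optional Gaussian timing noise."""
    if len(reference_ions) < 2:
        raise ValueError("need at least 2 reference ions")
    beta, t_fix = cal_truth
    proto = SingleFieldCalibration(
        beta=beta, t_fix=t_fix, r_squared=1.0, n_calibrants=2
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, _STREAM_TUNEMIX]))
    calibrants = []
    for mz, ref_ccs in reference_ions:
        t = ccs_to_drift(ref_ccs, mz, 1, proto)
        if noise_ms > 0:
            t += rng.normal(0.0, noise_ms)
        calibrants.append(CalibrantIon(mz=mz, z=1, reference_ccs=ref_ccs, t_a=t))
    return calibrants


def simulate_campaign(
    cfg: SimConfig,
) -> tuple[
    list[ChemicalRecord],
    list[TruthIon],
    pd.DataFrame,
    list[dict],
    SingleFieldCalibration,
]:
    """One-call campaign: registry, truth, noisy replicate features, artifact
    manifest, and the calibration fitted from a noiseless tune mix."""
    registry = generate_registry(cfg)
    truth = simulate_truth(registry, cfg)
    calibrants = generate_tune_mix((cfg.cal_beta, cfg.cal_t_fix), seed=cfg.seed)
    cal = fit_single_field(calibrants)
    features, manifest = simulate_runs(truth, cal, cfg)
    return registry, truth, features, manifest, cal
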