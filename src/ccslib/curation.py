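"""QC gating and library assembly for measured CCS values.

The curation pipeline mirrors how a reference CCS library is built from
replicate drift-tube measurements of chemical standards:

1. *Ion detection gate* — an ion is considered present only if the observed
   m/z lies within a ppm tolerance of the value expected from the chemical
   formula (default |ppm| < 10, strict) AND the observed (M+1)/M isotope
   ratio is consistent with the formula's 13C content.
2. *Replicate reproducibility gate* — at least two replicate CCS values
   must agree to within a percent-difference tolerance (default <= 1%);
   the reported CCS is the mean of the agreeing replicates.
3. *Trendline filter* — CCS grows as a power law of m/z within an ion
   type; entries further than a percent tolerance (default 15%) from the
   fitted trendline are rejected.  This removes multimer "streaking"
   artifacts: solution-phase multimers drift as multimers but are detected
   at monomer m/z, producing anomalously large CCS per m/z.
4. *Assembly* — surviving (chemical, ion type, mode) entries become the
   library; a conservation report accounts for every candidate in exactly
   one stage bucket.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .chem_ions import ElementCounts, IonType, TheoreticalIon, hill_formula, ppm_error

__all__ = [
    "ChemicalRecord",
    "ReplicateFeature",
    "IonDetection",
    "TrendlineModel",
    "LibraryEntry",
    "CurationReport",
    "CurationThresholds",
    "detect_ion",
    "classify_candidate",
    "percent_difference",
    "replicate_qc",
    "fit_trendline",
    "trendline_filter",
    "assemble_library",
]


@dataclass(frozen=True)
class ChemicalRecord:
    """One registry row: identifier, name, formula, class and optional
    stability / ESI-amenability flags (None = unknown)."""

    chem_id: str
    name: str
    formula: ElementCounts
    chem_class: str = "Unclassified"
    stable: bool | None = None
    amenable_esi_neg: bool | None = None
    amenable_esi_pos: bool | None = None


@dataclass(frozen=True)
class ReplicateFeature:
    """A single replicate observation of one chemical in one mode."""

    chem_id: str
    mode: str
    replicate_index: int
    observed_mz: float
    observed_m1_ratio: float
    ccs: float | None = None
    t_a: float | None = None

    def __post_init__(self) -> None:
        if self.observed_mz <= 0:
            raise ValueError("observed_mz must be positive")
        if (self.ccs is None) == (self.t_a is None):
            raise ValueError("exactly one of ccs / t_a must be provided")


@dataclass
class IonDetection:
    """Gate state for one (chemical, ion type, mode) candidate."""

    chem_id: str
    ion_type: IonType
    mode: str
    theoretical_mz: float
    ppm: float = math.nan
    isotope_ok: bool = False
    replicate_ccs: list[float] = field(default_factory=list)
    pct_diff: float = math.nan
    qc_pass: bool = False
    mean_ccs: float = math.nan
    status: str = "candidate"  # detected | no_mz_match | isotope_fail | replicate_fail | trendline_outlier | retained


@dataclass(frozen=True)
class TrendlineModel:
    """Power-law CCS-m/z trend: ccs = a * mz**b, fitted in log-log space."""

    a: float
    b: float
    mz_min: float
    mz_max: float
    scope: str = "global"

    def predict(self, mz: float | np.ndarray) -> float | np.ndarray:
        return self.a * np.asarray(mz, dtype=float) ** self.b


@dataclass(frozen=True)
class LibraryEntry:
    """One curated library row: a chemical's averaged CCS for one adduct
    in one ionization mode."""

    chem_id: str
    name: str
    formula: str
    chem_class: str
    ion_type: str
    mode: str
    mz: float
    ccs: float
    n_replicates: int
    pct_diff: float


@dataclass
class CurationReport:
    """Per-stage candidate counts; conserved: n_candidates equals the sum of
    retained and the four rejection buckets."""

    n_candidates: int = 0
    rejected_ppm: int = 0
    rejected_isotope: int = 0
    rejected_replicate: int = 0
    rejected_trendline: int = 0
    retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "n_candidates": self.n_candidates,
            "rejected_ppm": self.rejected_ppm,
            "rejected_isotope": self.rejected_isotope,
            "rejected_replicate": self.rejected_replicate,
            "rejected_trendline": self.rejected_trendline,
            "retained": self.retained,
        }

    @property
    def conserved(self) -> bool:
        return self.n_candidates == (
            self.rejected_ppm
            + self.rejected_isotope
            + self.rejected_replicate
            + self.rejected_trendline
            + self.retained
        )


@dataclass(frozen=True)
class CurationThresholds:
    """QC thresholds; defaults follow the library-curation convention:
    |ppm| < 10 (strict), isotope-ratio relative error <= 30%, replicate
    percent difference <= 1%, trendline residual <= 15%."""

    ppm_tol: float = 10.0
    isotope_rel_tol: float = 0.30
    replicate_tol: float = 1.0
    trendline_tol: float = 15.0
    trendline_min_points: int = 20

    def __post_init__(self) -> None:
        for name in ("ppm_tol", "isotope_rel_tol", "replicate_tol", "trendline_tol"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def detect_ion(
    features: Sequence[ReplicateFeature],
    theo: TheoreticalIon,
    cfg: CurationThresholds = CurationThresholds(),
) -> IonDetection | None:
    """Gate replicate features against an expected ion.

    A replicate matches when its mass error is strictly inside the ppm
    tolerance AND its observed (M+1)/M ratio is within ``isotope_rel_tol``
    relative error of the formula's expectation.  Returns ``None`` when no
    replicate matches (absence is a valid outcome); otherwise an
    :class:`IonDetection` carrying the CCS of every matching replicate and
    the mean signed ppm error.

    All features must share one chemical and one mode.
    """
    if not features:
        return None
    d = classify_candidate(features, theo, cfg)
    return d if d.status == "detected" else None


def classify_candidate(
    features: Sequence[ReplicateFeature],
    theo: TheoreticalIon,
    cfg: CurationThresholds = CurationThresholds(),
) -> IonDetection:
    """Like :func:`detect_ion` but always returns the candidate with its
    gate outcome recorded in ``status`` (for conservation accounting)."""
    if not features:
        raise ValueError("no features for candidate")
    if len({f.chem_id for f in features}) != 1 or len({f.mode for f in features}) != 1:
        raise ValueError("features must share chem_id and mode")
    d = IonDetection(
        chem_id=features[0].chem_id,
        ion_type=theo.ion_type,
        mode=features[0].mode,
        theoretical_mz=theo.mz,
    )
    mz_ok = [f for f in features if abs(ppm_error(f.observed_mz, theo.mz)) < cfg.ppm_tol]
    if not mz_ok:
        d.status = "no_mz_match"
        return d
    if theo.m1_ratio > 0:
        iso_ok = [
            f
            for f in mz_ok
            if abs(f.observed_m1_ratio - theo.m1_ratio) / theo.m1_ratio
            <= cfg.isotope_rel_tol
        ]
    else:
        iso_ok = [f for f in mz_ok if f.observed_m1_ratio <= cfg.isotope_rel_tol]
    if not iso_ok:
        d.status = "isotope_fail"
        return d
    d.status = "detected"
    d.isotope_ok = True
    d.ppm = float(np.mean([ppm_error(f.observed_mz, theo.mz) for f in iso_ok]))
    d.replicate_ccs = [f.ccs for f in iso_ok if f.ccs is not None]
    return d


def percent_difference(values: Sequence[float]) -> float:
    """Percent difference between replicate values.

    For two values: 100 |a - b| / mean(a, b) — the pair-mean denominator
    convention.  For more than two, the gate statistic is the percent
    difference of the best-agreeing pair (the minimum over pairs), since
    the reproducibility rule asks only that *some* two replicates agree.
    """
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    if any(v <= 0 for v in values):
        raise ValueError("values must be strictly positive")
    if len(values) == 2:
        a, b = values
        return 100.0 * abs(a - b) / ((a + b) / 2.0)
    return min(
        100.0 * abs(a - b) / ((a + b) / 2.0)
        for a, b in itertools.combinations(values, 2)
    )


def _largest_agreeing_subset(values: Sequence[float], tol: float) -> list[float]:
    """Largest subset whose pairwise percent differences are all <= tol."""
    best: tuple[float, ...] = ()
    for r in range(len(values), 1, -1):
        for sub in itertools.combinations(values, r):
            if all(
                100.0 * abs(a - b) / ((a + b) / 2.0) <= tol
                for a, b in itertools.combinations(sub, 2)
            ):
                best = sub
                break
        if best:
            break
    return list(best)


def replicate_qc(
    d: IonDetection, cfg: CurationThresholds = CurationThresholds()
) -> IonDetection:
    """Apply the replicate-reproducibility gate to a detection.

    Passes iff some pair of replicate CCS values agrees within
    ``replicate_tol`` percent; ``mean_ccs`` is the mean over the largest
    mutually agreeing subset.  A single replicate cannot confirm
    reproducibility and fails.
    """
    if len(d.replicate_ccs) < 2:
        d.qc_pass = False
        d.status = "replicate_fail"
        return d
    d.pct_diff = percent_difference(d.replicate_ccs)
    if d.pct_diff <= cfg.replicate_tol:
        subset = _largest_agreeing_subset(d.replicate_ccs, cfg.replicate_tol)
        d.qc_pass = True
        d.mean_ccs = float(np.mean(subset))
        d.status = "detected"
    else:
        d.qc_pass = False
        d.status = "replicate_fail"
    return d


def fit_trendline(
    points: Sequence[tuple[float, float]], scope: str = "global"
) -> TrendlineModel:
    """Least-squares power-law fit ccs = a * mz**b via log-log regression."""
    if len(points) < 3:
        raise ValueError("need at least 3 points to fit a trendline")
    mz = np.array([p[0] for p in points], dtype=float)
    ccs = np.array([p[1] for p in points], dtype=float)
    if np.any(mz <= 0) or np.any(ccs <= 0):
        raise ValueError("trendline coordinates must be strictly positive")
    b, log_a = np.polyfit(np.log(mz), np.log(ccs), 1)
    return TrendlineModel(
        a=float(np.exp(log_a)),
        b=float(b),
        mz_min=float(mz.min()),
        mz_max=float(mz.max()),
        scope=scope,
    )


def trendline_filter(
    entries: Iterable[IonDetection],
    model: TrendlineModel,
    tol: float = 15.0,
) -> tuple[list[IonDetection], list[IonDetection]]:
    """Split detections into (retained, rejected) by trendline residual.

    An entry is retained iff 100 |ccs - a mz^b| / (a mz^b) <= tol; rejected
    entries are flagged ``trendline_outlier``.  At +40% multimer inflation
    against a few-percent natural scatter the two populations are fully
    separable.
    """
    retained: list[IonDetection] = []
    rejected: list[IonDetection] = []
    for d in entries:
        pred = float(model.predict(_entry_mz(d)))
        resid_pct = 100.0 * abs(d.mean_ccs - pred) / pred
        if resid_pct <= tol:
            d.status = "retained"
            retained.append(d)
        else:
            d.status = "trendline_outlier"
            rejected.append(d)
    return retained, rejected


def _entry_mz(d: IonDetection) -> float:
    return d.theoretical_mz


def assemble_library(
    registry: Sequence[ChemicalRecord],
    detections: Sequence[IonDetection],
    cfg: CurationThresholds = CurationThresholds(),
) -> tuple[list[LibraryEntry], CurationReport]:
    """Build the final library from gate-classified candidates.

    ``detections`` must carry their full gate history in ``status``
    (as produced by :func:`classify_candidate`, :func:`replicate_qc` and
    :func:`trendline_filter`); only ``retained`` candidates become entries.
    Registry rows with a duplicated chem_id collapse to one chemical.
    Raises on a duplicate (chem_id, ion_type, mode) among retained
    candidates, which signals an upstream bug.
    """
    by_id: dict[str, ChemicalRecord] = {}
    for rec in registry:
        by_id.setdefault(rec.chem_id, rec)  # duplicates collapse to first

    report = CurationReport(n_candidates=len(detections))
    entries: list[LibraryEntry] = []
    seen: set[tuple[str, str, str]] = set()
    for d in detections:
        if d.status == "no_mz_match":
            report.rejected_ppm += 1
        elif d.status == "isotope_fail":
            report.rejected_isotope += 1
        elif d.status == "replicate_fail":
            report.rejected_replicate += 1
        elif d.status == "trendline_outlier":
            report.rejected_trendline += 1
        elif d.status == "retained":
            report.retained += 1
            key = (d.chem_id, d.ion_type.label, d.mode)
            if key in seen:
                raise ValueError(f"duplicate library key {key}: upstream bug")
            seen.add(key)
            rec = by_id.get(d.chem_id)
            if rec is None:
                raise KeyError(f"chem_id {d.chem_id!r} missing from registry")
            entries.append(
                LibraryEntry(
                    chem_id=d.chem_id,
                    name=rec.name,
                    formula=hill_formula(rec.formula),
                    chem_class=rec.chem_class,
                    ion_type=d.ion_type.label,
                    mode=d.mode,
                    mz=round(d.theoretical_mz, 4),
                    ccs=round(d.mean_ccs, 2),
                    n_replicates=len(d.replicate_ccs),
                    pct_diff=round(d.pct_diff, 3),
                )
            )
        else:
            raise ValueError(f"candidate with unclassified status {d.status!r}")
    return entries, report
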