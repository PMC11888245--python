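"""Detection-frequency summaries and detection-vs-flag association tests.

Given a chemical registry and a curated library, this module counts which
chemicals were detected per ionization mode and chemical class, the
three-mode Venn overlap, and cross-tabulates detection against stability or
predicted ESI amenability flags, testing the association with Fisher's
exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import scipy.stats

from .chem_ions import MODES
from .curation import ChemicalRecord, LibraryEntry

__all__ = [
    "TwoByTwo",
    "DetectionSummary",
    "detection_summary",
    "fisher_exact",
    "crosstab_fractions",
    "flag_association",
]


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 detection-by-flag contingency table.

    Layout: rows = flag true/false, columns = detected yes/no:
    a = flag & detected, b = flag & not detected,
    c = no-flag & detected, d = no-flag & not detected.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table is all zero")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return (self.a * self.d) / (self.b * self.c)


@dataclass
class DetectionSummary:
    """Per-class / per-mode detection counts and three-mode Venn cells."""

    n_registry: int
    n_detected: int
    per_class: dict[str, dict[str, int]] = field(default_factory=dict)
    mode_totals: dict[str, int] = field(default_factory=dict)
    venn: dict[str, int] = field(default_factory=dict)

    @property
    def detected_fraction_pct(self) -> float:
        if self.n_registry == 0:
            return 0.0
        return 100.0 * self.n_detected / self.n_registry

    def mode_only(self, mode: str) -> int:
        return self.venn.get(mode, 0)


def _venn_key(modes: frozenset[str]) -> str:
    return "&".join(sorted(modes))


def detection_summary(
    registry: Sequence[ChemicalRecord],
    library: Sequence[LibraryEntry],
    modes: Sequence[str] = MODES,
) -> DetectionSummary:
    """Count unique chemicals detected per mode, per class, and the Venn
    overlap of the three modes.

    A chemical counts as detected in a mode if it has at least one library
    entry in that mode; duplicated registry ids collapse to one chemical.
    Raises on a library chem_id absent from the registry.
    """
    by_id: dict[str, ChemicalRecord] = {}
    for rec in registry:
        by_id.setdefault(rec.chem_id, rec)

    detected_modes: dict[str, set[str]] = {}
    for e in library:
        if e.chem_id not in by_id:
            raise KeyError(f"library chem_id {e.chem_id!r} not in registry")
        detected_modes.setdefault(e.chem_id, set()).add(e.mode)

    summary = DetectionSummary(n_registry=len(by_id), n_detected=len(detected_modes))
    summary.mode_totals = {m: 0 for m in modes}
    for mode_set in detected_modes.values():
        for m in mode_set:
            summary.mode_totals[m] += 1
    # 7 non-empty subsets of the 3 modes
    venn: dict[str, int] = {}
    for mode_set in detected_modes.values():
        venn[_venn_key(frozenset(mode_set))] = (
            venn.get(_venn_key(frozenset(mode_set)), 0) + 1
        )
    summary.venn = venn

    classes = sorted({rec.chem_class for rec in by_id.values()})
    for cls in classes:
        ids = [cid for cid, rec in by_id.items() if rec.chem_class == cls]
        row = {"tested": len(ids), "detected": sum(1 for c in ids if c in detected_modes)}
        for m in modes:
            row[m] = sum(1 for c in ids if m in detected_modes.get(c, set()))
        summary.per_class[cls] = row
    return summary


def fisher_exact(table: TwoByTwo) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table.

    Uses the point-probability rule: sum of hypergeometric probabilities of
    all tables (with the observed margins) no more probable than the
    observed one — the convention of mainstream statistics tools.
    """
    res = scipy.stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    return float(res.pvalue)


def crosstab_fractions(
    registry: Sequence[ChemicalRecord],
    library: Sequence[LibraryEntry],
    flag: str,
) -> tuple[dict[str, Fraction], int, TwoByTwo]:
    """Cross-tabulate detection (any mode, or the flag's own mode for
    amenability) against a boolean registry flag.

    ``flag`` is ``"stable"``, ``"amenable_esi_neg"`` or
    ``"amenable_esi_pos"``.  Chemicals with a missing flag are excluded
    listwise from n.  For the amenability flags, "detected" means detected
    in the corresponding ESI mode; for stability it means detected in any
    mode.  Fractions are exact rationals over the included n and sum to 1.
    """
    flag_mode = {"amenable_esi_neg": "ESI-", "amenable_esi_pos": "ESI+"}.get(flag)
    by_id: dict[str, ChemicalRecord] = {}
    for rec in registry:
        by_id.setdefault(rec.chem_id, rec)
    detected_modes: dict[str, set[str]] = {}
    for e in library:
        detected_modes.setdefault(e.chem_id, set()).add(e.mode)

    a = b = c = d = 0
    for cid, rec in by_id.items():
        val = getattr(rec, flag)
        if val is None:
            continue
        modes = detected_modes.get(cid, set())
        det = (flag_mode in modes) if flag_mode else bool(modes)
        if val and det:
            a += 1
        elif val and not det:
            b += 1
        elif det:
            c += 1
        else:
            d += 1
    n = a + b + c + d
    if n == 0:
        raise ValueError(f"no non-missing values for flag {flag!r}")
    table = TwoByTwo(a, b, c, d)
    fractions = {
        "flag_detected": Fraction(a, n),
        "flag_not_detected": Fraction(b, n),
        "noflag_detected": Fraction(c, n),
        "noflag_not_detected": Fraction(d, n),
    }
    assert sum(fractions.values()) == 1
    return fractions, n, table


def flag_association(
    registry: Sequence[ChemicalRecord],
    library: Sequence[LibraryEntry],
    flag: str,
) -> dict:
    """Convenience bundle: cross-tab fractions, n, odds ratio and Fisher p."""
    fractions, n, table = crosstab_fractions(registry, library, flag)
    return {
        "flag": flag,
        "n": n,
        "fractions": {k: float(v) for k, v in fractions.items()},
        "odds_ratio": table.odds_ratio,
        "p_value": fisher_exact(table),
        "table": [[table.a, table.b], [table.c, table.d]],
    }
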