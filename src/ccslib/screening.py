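"""Suspect screening against a CCS library and inter-library comparison.

Suspect screening matches measured (m/z, CCS) features to library entries
inside a ppm mass window and (when the query carries a CCS) a percent CCS
window, without per-sample standards.  Inter-library comparison quantifies
reproducibility of CCS values between two libraries using the pairwise
percent difference, binned at the community's 2% (instrument variability)
and 5% (method differences) thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .curation import LibraryEntry, percent_difference

__all__ = [
    "QueryFeature",
    "ScreenHit",
    "PairwiseComparison",
    "suspect_screen",
    "compare_libraries",
]


@dataclass(frozen=True)
class QueryFeature:
    """A measured feature to screen: m/z, optionally CCS and intensity."""

    query_id: str
    mode: str
    mz: float
    ccs: float | None = None
    intensity: float | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("query mz must be positive")


@dataclass(frozen=True)
class ScreenHit:
    """A library match for a query, with its mass and CCS deviations and a
    dimensionless rank score (0 = perfect match)."""

    query_id: str
    chem_id: str
    name: str
    ion_type: str
    mode: str
    ppm: float
    delta_ccs_pct: float | None
    score: float


@dataclass
class PairwiseComparison:
    """Matched CCS pairs between two libraries with percent differences
    binned at <=2%, (2%, 5%] and >5%."""

    pairs: list[dict] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.pairs)

    @property
    def bin_counts(self) -> dict[str, int]:
        counts = {"<=2%": 0, "(2%,5%]": 0, ">5%": 0}
        for p in self.pairs:
            d = p["pct_diff"]
            if d <= 2.0:
                counts["<=2%"] += 1
            elif d <= 5.0:
                counts["(2%,5%]"] += 1
            else:
                counts[">5%"] += 1
        return counts

    @property
    def bin_fractions(self) -> dict[str, float]:
        if not self.pairs:
            raise ValueError("no matched pairs")
        return {k: v / self.n for k, v in self.bin_counts.items()}


def suspect_screen(
    query: QueryFeature,
    library: Sequence[LibraryEntry],
    ppm_tol: float = 10.0,
    ccs_tol: float = 2.0,
    match_mode: bool = True,
) -> list[ScreenHit]:
    """Rank library entries matching a query feature.

    A hit must lie inside the m/z window (|ppm| <= ``ppm_tol``) and, when
    the query provides a CCS, inside the CCS window (|dCCS%| <= ``ccs_tol``,
    percent deviation relative to the library value).  Hits are ranked by

        score = (|ppm| / ppm_tol)^2 + (|dCCS%| / ccs_tol)^2

    ascending — a normalised quadratic that is invariant to the tolerance
    scales — with ties broken by |ppm| then chem_id.  An empty list is a
    valid outcome.
    """
    hits: list[ScreenHit] = []
    for e in library:
        if match_mode and e.mode != query.mode:
            continue
        ppm = 1e6 * (query.mz - e.mz) / e.mz
        if abs(ppm) > ppm_tol:
            continue
        delta_ccs = None
        score = (abs(ppm) / ppm_tol) ** 2
        if query.ccs is not None:
            delta_ccs = 100.0 * (query.ccs - e.ccs) / e.ccs
            if abs(delta_ccs) > ccs_tol:
                continue
            score += (abs(delta_ccs) / ccs_tol) ** 2
        hits.append(
            ScreenHit(
                query_id=query.query_id,
                chem_id=e.chem_id,
                name=e.name,
                ion_type=e.ion_type,
                mode=e.mode,
                ppm=ppm,
                delta_ccs_pct=delta_ccs,
                score=score,
            )
        )
    hits.sort(key=lambda h: (h.score, abs(h.ppm), h.chem_id))
    return hits


def compare_libraries(
    library_a: Sequence[LibraryEntry],
    library_b: Sequence[LibraryEntry],
    join: str = "chem_id",
) -> PairwiseComparison:
    """Join two libraries and bin the CCS percent differences.

    ``join`` is ``"chem_id"`` (default; key = chem_id + ion_type) or
    ``"formula"`` (key = formula + ion_type, for libraries that do not
    share an identifier scheme).  The percent difference uses the pair-mean
    denominator, so the comparison is symmetric in A and B.  Raises when no
    pair is joinable, which signals a key mismatch.
    """
    if join not in ("chem_id", "formula"):
        raise ValueError("join must be 'chem_id' or 'formula'")

    def key(e: LibraryEntry) -> tuple[str, str]:
        return ((e.chem_id if join == "chem_id" else e.formula), e.ion_type)

    index_b: dict[tuple[str, str], list[LibraryEntry]] = {}
    for e in library_b:
        index_b.setdefault(key(e), []).append(e)

    comparison = PairwiseComparison()
    for ea in library_a:
        for eb in index_b.get(key(ea), []):
            comparison.pairs.append(
                {
                    "chem_id": ea.chem_id,
                    "ion_type": ea.ion_type,
                    "ccs_a": ea.ccs,
                    "ccs_b": eb.ccs,
                    "pct_diff": percent_difference([ea.ccs, eb.ccs])
                    if ea.ccs != eb.ccs
                    else 0.0,
                }
            )
    if not comparison.pairs:
        raise ValueError("no joinable pairs between libraries (key mismatch?)")
    return comparison
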