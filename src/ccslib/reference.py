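"""Campaign-level arithmetic on published aggregate counts.

A measurement campaign reports a handful of headline numbers — how many
standards were plated, how many were plate duplicates, how many unique
chemicals yielded reproducible CCS values, per-mode totals.  This module
loads such a summary table (one ships with the package) and recomputes the
derived quantities from the raw counts: unique chemicals after duplicate
collapsing, the detected fraction, and the class-count total.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

__all__ = [
    "load_campaign_summary",
    "unique_chemicals",
    "detected_fraction_pct",
    "class_count_total",
]


def load_campaign_summary(path: str | Path | None = None) -> dict:
    """Load a campaign summary JSON; defaults to the bundled table."""
    if path is not None:
        return json.loads(Path(path).read_text())
    with resources.files("ccslib.data").joinpath("campaign_summary.json").open() as fh:
        return json.load(fh)


def unique_chemicals(summary: dict) -> int:
    """Unique chemicals = plated standards minus plate duplicates."""
    return int(summary["n_standards"]) - int(summary["n_plate_duplicates"])


def detected_fraction_pct(summary: dict) -> float:
    """Percent of unique chemicals detected in at least one mode."""
    return 100.0 * int(summary["n_detected_unique"]) / unique_chemicals(summary)


def class_count_total(summary: dict) -> int:
    """Sum of the per-class standard counts (should equal n_standards)."""
    return sum(int(v) for v in summary["class_counts"].values())
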