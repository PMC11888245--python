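"""Pipeline configuration: thresholds, file paths and column mappings.

A single structured YAML file holds every tunable threshold with its
default; CLI flags override file values.  The config round-trips through
YAML losslessly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .curation import CurationThresholds

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """All pipeline thresholds and I/O settings.

    Threshold defaults follow the curation conventions: |ppm| < 10 for the
    mass gate, 30% relative tolerance on the (M+1)/M isotope ratio, <= 1%
    replicate percent difference, <= 15% trendline residual, 10 ppm / 2%
    screening windows and 2%/5% inter-library comparison bins.
    """

    ppm_tol: float = 10.0
    isotope_rel_tol: float = 0.30
    replicate_tol: float = 1.0
    trendline_tol: float = 15.0
    trendline_min_points: int = 20
    screen_ppm_tol: float = 10.0
    screen_ccs_tol: float = 2.0
    interlab_bins: tuple[float, float] = (2.0, 5.0)
    seed: int = 0
    # optional file paths
    registry: str | None = None
    features: str | None = None
    calibrants: str | None = None
    out_dir: str = "."
    # column mapping for external library layouts (canonical -> file column)
    library_layout: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "ppm_tol",
            "isotope_rel_tol",
            "replicate_tol",
            "trendline_tol",
            "screen_ppm_tol",
            "screen_ccs_tol",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if tuple(self.interlab_bins) != (2.0, 5.0) and not (
            0 < self.interlab_bins[0] < self.interlab_bins[1]
        ):
            raise ValueError("interlab_bins must be increasing and positive")
        self.interlab_bins = tuple(self.interlab_bins)

    def thresholds(self) -> CurationThresholds:
        return CurationThresholds(
            ppm_tol=self.ppm_tol,
            isotope_rel_tol=self.isotope_rel_tol,
            replicate_tol=self.replicate_tol,
            trendline_tol=self.trendline_tol,
            trendline_min_points=self.trendline_min_points,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["interlab_bins"] = list(self.interlab_bins)
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected to catch typos."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    if "interlab_bins" in raw:
        raw["interlab_bins"] = tuple(raw["interlab_bins"])
    return PipelineConfig(**raw)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
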