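"""End-to-end curation: calibrate, detect, replicate-QC, trendline-filter,
assemble.

This is the orchestration layer over :mod:`ccslib.curation`: it converts
drift times to CCS with a single-field calibration, matches replicate
feature rows to the expected adducts of each registry chemical, applies the
three QC gates in order, and returns the curated library together with a
conserved per-stage report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .ccs_core import SingleFieldCalibration, drift_to_ccs
from .chem_ions import MODE_ION_TYPES, TheoreticalIon, theoretical_ion
from .curation import (
    ChemicalRecord,
    CurationReport,
    CurationThresholds,
    IonDetection,
    LibraryEntry,
    ReplicateFeature,
    TrendlineModel,
    assemble_library,
    classify_candidate,
    fit_trendline,
    replicate_qc,
    trendline_filter,
)

__all__ = ["CurationResult", "curate"]


@dataclass
class CurationResult:
    """Curated library plus full gate history and fitted trendlines."""

    entries: list[LibraryEntry]
    report: CurationReport
    detections: list[IonDetection] = field(default_factory=list)
    trendlines: dict[str, TrendlineModel] = field(default_factory=dict)

    @property
    def library(self) -> pd.DataFrame:
        from .io import library_to_frame

        return library_to_frame(self.entries)


def _features_from_frame(
    df: pd.DataFrame, cal: SingleFieldCalibration | None
) -> list[ReplicateFeature]:
    has_t = "t_A_ms" in df.columns and df["t_A_ms"].notna()
    has_ccs = "ccs_A2" in df.columns and df["ccs_A2"].notna()
    feats: list[ReplicateFeature] = []
    for i, row in df.iterrows():
        if "ccs_A2" in df.columns and pd.notna(row.get("ccs_A2")):
            ccs, t_a = float(row["ccs_A2"]), None
        elif "t_A_ms" in df.columns and pd.notna(row.get("t_A_ms")):
            if cal is None:
                raise ValueError(
                    "features carry drift times but no calibration was provided"
                )
            t = float(row["t_A_ms"])
            ccs = drift_to_ccs(t, float(row["observed_mz"]), 1, cal)
            t_a = None  # converted; store as ccs
        else:
            raise ValueError(f"feature row {i} has neither ccs_A2 nor t_A_ms")
        feats.append(
            ReplicateFeature(
                chem_id=str(row["chem_id"]),
                mode=str(row["mode"]),
                replicate_index=int(row["replicate_index"]),
                observed_mz=float(row["observed_mz"]),
                observed_m1_ratio=float(row["observed_m1_ratio"]),
                ccs=ccs,
            )
        )
    return feats


def curate(
    registry: list[ChemicalRecord],
    features: pd.DataFrame,
    cal: SingleFieldCalibration | None = None,
    cfg: CurationThresholds = CurationThresholds(),
) -> CurationResult:
    """Run the full curation pipeline on a replicate feature table.

    ``features`` columns: chem_id, mode, replicate_index, observed_mz,
    observed_m1_ratio, and one of t_A_ms (requires ``cal``) or ccs_A2.

    Feature rows are grouped per (chemical, mode); within a group each row
    is assigned to the nearest expected adduct m/z of that mode, and each
    (chemical, mode, adduct) candidate then passes through the ppm +
    isotope gate, the replicate-reproducibility gate, and the per-ion-type
    trendline filter (global fallback below ``cfg.trendline_min_points``
    points).  Candidate counts are conserved across report buckets.
    """
    by_id: dict[str, ChemicalRecord] = {}
    for rec in registry:
        by_id.setdefault(rec.chem_id, rec)

    feats = _features_from_frame(features, cal)
    groups: dict[tuple[str, str], list[ReplicateFeature]] = {}
    for f in feats:
        groups.setdefault((f.chem_id, f.mode), []).append(f)

    detections: list[IonDetection] = []
    for (chem_id, mode), rows in sorted(groups.items()):
        rec = by_id.get(chem_id)
        if rec is None:
            raise KeyError(f"feature chem_id {chem_id!r} not in registry")
        if mode not in MODE_ION_TYPES:
            raise ValueError(f"unknown ionization mode {mode!r}")
        theos: dict[str, TheoreticalIon] = {
            label: theoretical_ion(rec.formula, label)
            for label in MODE_ION_TYPES[mode]
        }
        assigned: dict[str, list[ReplicateFeature]] = {label: [] for label in theos}
        for f in rows:
            nearest = min(theos, key=lambda lb: abs(f.observed_mz - theos[lb].mz))
            assigned[nearest].append(f)
        for label, sub in assigned.items():
            if not sub:
                continue
            d = classify_candidate(sub, theos[label], cfg)
            if d.status == "detected":
                d = replicate_qc(d, cfg)
            detections.append(d)

    # trendline stage on QC-passed detections
    passed = [d for d in detections if d.status == "detected" and d.qc_pass]
    trendlines: dict[str, TrendlineModel] = {}
    if len(passed) >= 3:
        global_model = fit_trendline(
            [(d.theoretical_mz, d.mean_ccs) for d in passed], scope="global"
        )
        trendlines["global"] = global_model
        by_type: dict[str, list[IonDetection]] = {}
        for d in passed:
            by_type.setdefault(d.ion_type.label, []).append(d)
        for label, ds in by_type.items():
            if len(ds) >= cfg.trendline_min_points:
                model = fit_trendline(
                    [(d.theoretical_mz, d.mean_ccs) for d in ds], scope=label
                )
                trendlines[label] = model
            else:
                model = global_model
            trendline_filter(ds, model, cfg.trendline_tol)
    else:
        for d in passed:  # too few points to define a trendline: retain
            d.status = "retained"

    entries, report = assemble_library(registry, detections, cfg)
    return CurationResult(
        entries=entries, report=report, detections=detections, trendlines=trendlines
    )
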