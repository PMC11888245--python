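"""Tabular I/O: registry and feature CSVs, calibrant tables, library TSVs
(including externally published layouts via column mappings), and JSON
reports.

All tabular formats are header-required and delimiter-declared; there are
no positional columns.  The library TSV round-trips losslessly (CCS kept to
2 decimals).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .ccs_core import CalibrantIon
from .chem_ions import ION_TYPES, parse_formula
from .curation import ChemicalRecord, LibraryEntry

__all__ = [
    "read_registry",
    "write_registry",
    "read_features",
    "read_calibrants",
    "read_library",
    "write_library",
    "library_to_frame",
    "frame_to_library",
    "write_json",
    "normalize_ion_label",
]

LIBRARY_COLUMNS = [
    "chem_id",
    "name",
    "formula",
    "chem_class",
    "ion_type",
    "mode",
    "mz",
    "ccs_A2",
    "n_replicates",
    "pct_diff",
]

#: unicode minus / middle-dot variants seen in published library files
_ION_ALIASES = {
    "[M+H]+": "[M+H]+",
    "[M+Na]+": "[M+Na]+",
    "[M-H]-": "[M-H]-",
    "[M−H]−": "[M-H]-",
    "[M−H]-": "[M-H]-",
    "[M-H]−": "[M-H]-",
    "[M+]+": "[M+]+",
    "[M+]+·": "[M+]+",
    "[M+]+.": "[M+]+",
}

#: default mode per ion type when a library layout lacks a mode column
_ION_DEFAULT_MODE = {
    "[M-H]-": "ESI-",
    "[M+Na]+": "ESI+",
    "[M+H]+": "ESI+",
    "[M+]+": "APCI+",
}


def normalize_ion_label(label: str) -> str:
    label = label.strip()
    if label not in _ION_ALIASES:
        raise ValueError(f"unrecognized ion type label {label!r}")
    return _ION_ALIASES[label]


def _parse_flag(value) -> bool | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip().lower()
    if s in ("", "nan", "none"):
        return None
    if s in ("1", "true", "t", "yes", "y", "stable", "amenable"):
        return True
    if s in ("0", "false", "f", "no", "n", "unstable", "not amenable"):
        return False
    raise ValueError(f"cannot parse boolean flag {value!r}")


def read_registry(path: str | Path) -> list[ChemicalRecord]:
    """Read a chemical registry CSV (chem_id, name, formula, chem_class,
    stable, amenable_esi_neg, amenable_esi_pos; blanks mean unknown)."""
    df = pd.read_csv(path, dtype=str)
    required = {"chem_id", "name", "formula"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"registry {path} missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            ChemicalRecord(
                chem_id=row["chem_id"],
                name=row["name"],
                formula=parse_formula(row["formula"]),
                chem_class=row.get("chem_class") or "Unclassified",
                stable=_parse_flag(row.get("stable")),
                amenable_esi_neg=_parse_flag(row.get("amenable_esi_neg")),
                amenable_esi_pos=_parse_flag(row.get("amenable_esi_pos")),
            )
        )
    return records


def write_registry(records: Sequence[ChemicalRecord], path: str | Path) -> None:
    from .chem_ions import hill_formula

    def flag(v):
        return "" if v is None else str(bool(v)).lower()

    df = pd.DataFrame(
        {
            "chem_id": [r.chem_id for r in records],
            "name": [r.name for r in records],
            "formula": [hill_formula(r.formula) for r in records],
            "chem_class": [r.chem_class for r in records],
            "stable": [flag(r.stable) for r in records],
            "amenable_esi_neg": [flag(r.amenable_esi_neg) for r in records],
            "amenable_esi_pos": [flag(r.amenable_esi_pos) for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    """Read a replicate feature CSV (chem_id, mode, replicate_index,
    observed_mz, observed_m1_ratio, and t_A_ms or ccs_A2)."""
    df = pd.read_csv(path)
    required = {"chem_id", "mode", "replicate_index", "observed_mz", "observed_m1_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"features {path} missing columns: {sorted(missing)}")
    if "t_A_ms" not in df.columns and "ccs_A2" not in df.columns:
        raise ValueError(f"features {path} need a t_A_ms or ccs_A2 column")
    return df


def read_calibrants(path: str | Path) -> list[CalibrantIon]:
    """Read a calibrant CSV (mz, z, reference_ccs_A2, t_A_ms)."""
    df = pd.read_csv(path)
    required = {"mz", "z", "reference_ccs_A2", "t_A_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibrant table {path} missing columns: {sorted(missing)}")
    return [
        CalibrantIon(
            mz=float(r["mz"]),
            z=int(r["z"]),
            reference_ccs=float(r["reference_ccs_A2"]),
            t_a=float(r["t_A_ms"]),
        )
        for _, r in df.iterrows()
    ]


def library_to_frame(entries: Sequence[LibraryEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chem_id": e.chem_id,
                "name": e.name,
                "formula": e.formula,
                "chem_class": e.chem_class,
                "ion_type": e.ion_type,
                "mode": e.mode,
                "mz": e.mz,
                "ccs_A2": e.ccs,
                "n_replicates": e.n_replicates,
                "pct_diff": e.pct_diff,
            }
            for e in entries
        ],
        columns=LIBRARY_COLUMNS,
    )


def frame_to_library(df: pd.DataFrame) -> list[LibraryEntry]:
    entries = []
    for _, r in df.iterrows():
        entries.append(
            LibraryEntry(
                chem_id=str(r["chem_id"]),
                name=str(r.get("name", "")),
                formula=str(r.get("formula", "")),
                chem_class=str(r.get("chem_class", "Unclassified")),
                ion_type=normalize_ion_label(str(r["ion_type"])),
                mode=str(r["mode"]),
                mz=float(r["mz"]),
                ccs=float(r["ccs_A2"]),
                n_replicates=int(r.get("n_replicates", 0) or 0),
                pct_diff=float(r["pct_diff"]) if pd.notna(r.get("pct_diff")) else float("nan"),
            )
        )
    return entries


def write_library(entries: Sequence[LibraryEntry], path: str | Path) -> None:
    """Write the curated library as TSV (CCS to 2 decimals)."""
    df = library_to_frame(entries)
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_library(
    path: str | Path,
    layout: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> list[LibraryEntry]:
    """Read a library table, optionally through a column mapping.

    ``layout`` maps canonical field names (chem_id, ion_type, mz, ccs_A2,
    and optionally name, formula, chem_class, mode, n_replicates, pct_diff)
    to the file's column names, so externally published layouts (e.g. a
    supplementary table with "DTXSID" / "Ion Type" / "Average CCS" headers)
    can be ingested directly.  When the layout lacks a mode column, the
    mode is inferred from the ion type ([M-H]- -> ESI-, [M+]+ -> APCI+,
    protonated/sodiated -> ESI+).
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=delimiter)
    if layout:
        rename = {src: dst for dst, src in layout.items()}
        missing = [src for src in rename if src not in df.columns]
        if missing:
            raise ValueError(f"library {path} missing mapped columns: {missing}")
        df = df.rename(columns=rename)
    for col in ("chem_id", "ion_type", "mz", "ccs_A2"):
        if col not in df.columns:
            raise ValueError(f"library {path} missing required column {col!r}")
    df["ion_type"] = df["ion_type"].map(normalize_ion_label)
    if "mode" not in df.columns:
        df["mode"] = df["ion_type"].map(_ION_DEFAULT_MODE)
    return frame_to_library(df)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
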