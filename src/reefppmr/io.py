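"""Tabular I/O: CSV readers/writers with validated headers, truth sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

GUT_COLUMNS = [
    "predator_id", "species", "genus", "guild", "predator_mass_g",
    "prey_taxon", "prey_length_mm",
]
ALLOMETRY_COLUMNS = [
    "taxon", "a", "b", "length_unit", "dry_flag", "dry_to_wet_factor",
]
SURVEY_COLUMNS = [
    "transect_id", "site", "year", "sst_c", "species", "guild",
    "size_class_cm", "abundance", "lw_a", "lw_b",
]
CPPMR_COLUMNS = [
    "transect_id", "site", "year", "sst_c", "cppmr", "log10_cppmr",
    "n_individuals",
]


def _read_csv(path, required: list[str], label: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{label} file not found: {path}")
    df = pd.read_csv(path)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(
            f"{label} file {path} is missing columns {sorted(missing)}"
        )
    return df


def read_gut_csv(path) -> pd.DataFrame:
    return _read_csv(path, GUT_COLUMNS, "gut-content")


def read_allometry_csv(path) -> pd.DataFrame:
    return _read_csv(path, ALLOMETRY_COLUMNS, "allometry")


def read_survey_csv(path) -> pd.DataFrame:
    return _read_csv(path, SURVEY_COLUMNS, "survey")


def write_csv(df: pd.DataFrame, path) -> Path:
    """Deterministic CSV export (fixed float format, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def write_truth_json(truth: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    return path
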