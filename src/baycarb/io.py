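"""Delimited-text readers/writers and run configuration.

All tables are plain delimited text (comma by default) with explicit
header names; readers validate the schema up front and report offending
columns/rows rather than failing downstream.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "read_station_table",
    "write_speciation_table",
    "read_nubbin_table",
    "read_incubation_table",
    "read_point_count_table",
    "load_config",
    "ConfigError",
]

STATION_COLUMNS = [
    "site_id", "phase", "salinity", "temperature_c", "ta_umol_kg", "dic_umol_kg",
]
SPECIATION_COLUMNS = STATION_COLUMNS + [
    "ph_total", "pco2_uatm", "omega_arag",
    "co2_umol_kg", "hco3_umol_kg", "co3_umol_kg",
]
NUBBIN_COLUMNS = [
    "nubbin_id", "colony_id", "origin_site", "transplant_site",
    "buoyant_weight_initial_g", "buoyant_weight_final_g",
    "duration_days", "surface_area_cm2",
]
INCUBATION_COLUMNS = [
    "nubbin_id", "phase", "chamber_volume_ml", "coral_volume_ml",
    "time_min", "o2_umol_l",
]
POINT_COUNT_COLUMNS = [
    "site_id", "transect_id", "photo_id", "point_index", "category",
]


class ConfigError(ValueError):
    """Missing or malformed run-configuration entry."""


def _read(path, required, sep=","):
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_station_table(path, sep: str = ",") -> pd.DataFrame:
    """Station water-chemistry table; keeps any extra columns such as
    station_role, lat, lon or depth."""
    df = _read(path, STATION_COLUMNS, sep)
    bad_phase = set(df["phase"]) - {"day", "night"}
    if bad_phase:
        raise ValueError(f"{path}: phase must be day|night, got {sorted(bad_phase)}")
    return df


def write_speciation_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    ordered = [c for c in SPECIATION_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in SPECIATION_COLUMNS
    ]
    df[ordered].to_csv(path, sep=sep, index=False)


def read_nubbin_table(path, sep: str = ",") -> pd.DataFrame:
    return _read(path, NUBBIN_COLUMNS, sep)


def read_incubation_table(path, sep: str = ",") -> pd.DataFrame:
    df = _read(path, INCUBATION_COLUMNS, sep)
    if "is_blank" not in df.columns:
        df["is_blank"] = False
    return df


def read_point_count_table(path, sep: str = ",") -> pd.DataFrame:
    return _read(path, POINT_COUNT_COLUMNS, sep)


def load_config(path) -> dict:
    """YAML run configuration; top level must be a mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return cfg


def require(cfg: dict, key: str, context: str = "config"):
    """Fetch a required (possibly dotted) key with a named error."""
    node = cfg
    for part in key.split("."):
        if not isinstance(node, dict) or part not in node:
            raise ConfigError(f"{context}: missing required key {key!r}")
        node = node[part]
    return node
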