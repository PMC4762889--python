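"""Delimited-text input/output for the pipeline tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synth import BIOMASS_COLUMNS

__all__ = ["PLOT_COLUMNS", "CLIMATE_COLUMNS", "read_plots", "write_plots",
           "read_climate", "write_climate", "read_biomass", "write_biomass"]

PLOT_COLUMNS = ["plot_id", "district", "region", "area_ha", "species",
                "site_class", "age", "org_layer_m", "first_year", "history"]
CLIMATE_COLUMNS = ["plot_id", "year", "mat", "t_min", "t_max", "precip_mm"]


def _read(path, columns: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return frame[columns]


def _write(frame: pd.DataFrame, path, columns: list[str]) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"cannot write {path}: missing columns {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame[columns].to_csv(path, sep="\t", index=False)


def read_plots(path) -> pd.DataFrame:
    return _read(path, PLOT_COLUMNS)


def write_plots(frame: pd.DataFrame, path) -> None:
    _write(frame, path, PLOT_COLUMNS)


def read_climate(path) -> pd.DataFrame:
    frame = _read(path, CLIMATE_COLUMNS)
    if (frame["precip_mm"] < 0).any():
        raise ValueError(f"{path}: negative precipitation")
    return frame


def write_climate(frame: pd.DataFrame, path) -> None:
    _write(frame, path, CLIMATE_COLUMNS)


def read_biomass(path) -> pd.DataFrame:
    frame = _read(path, BIOMASS_COLUMNS)
    value_cols = [c for c in BIOMASS_COLUMNS if c not in ("plot_id", "year")]
    if (frame[value_cols] < 0).to_numpy().any():
        raise ValueError(f"{path}: negative biomass entries")
    return frame


def write_biomass(frame: pd.DataFrame, path) -> None:
    _write(frame, path, BIOMASS_COLUMNS)
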