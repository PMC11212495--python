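"""CSV readers and writers for the demographic input dialects.

All files are plain CSV with optional ``# key: value`` metadata lines before
the header.  Metadata carries what a bare table cannot: the life-table radix
and the unit convention of rate/ratio columns, so that per-1000 inputs are
normalised exactly once, on read.

Dialects
--------
life table : columns ``age_start, age_interval, lx, Lx``;
    metadata ``radix`` (default 100000) and optional ``lx_end``.
fertility  : columns ``age_start, age_interval, asfr``;
    metadata ``units`` in {per_woman, per_1000}.
morbidity  : columns ``age_start, age_interval, cases, live_births`` and/or
    ``ratio``; metadata ``units`` in {per_birth, per_1000, per_100000}.

World Population Prospects CSV exports use different column names; pass a
``column_map`` (e.g. ``{"AgeGrpStart": "age_start", "Lx": "Lx", ...}``) to
rename them on load.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .demog import (
    RATE_UNITS,
    RATIO_UNITS,
    AbridgedLifeTable,
    AgeGrid,
    FertilitySchedule,
    MorbiditySchedule,
)
from .errors import InputError

_AGE_COLS = ["age_start", "age_interval"]


def _read_metadata(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
    return meta


def _read_table(
    path: str | Path, required: list[str], column_map: Mapping[str, str] | None
) -> tuple[pd.DataFrame, dict[str, str]]:
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}; found {list(df.columns)}")
    return df, meta


def _grid_from(df: pd.DataFrame) -> AgeGrid:
    return AgeGrid(tuple(df["age_start"].astype(float)), tuple(df["age_interval"].astype(float)))


def parse_age_label(label: str) -> tuple[float, float]:
    """Parse '15-19' / '15–19' style labels into (start, interval length)."""
    for dash in ("–", "—", "-"):
        if dash in str(label):
            lo, _, hi = str(label).partition(dash)
            try:
                start, end = float(lo), float(hi)
            except ValueError:
                break
            return start, end - start + 1
    raise InputError(f"cannot parse age-group label {label!r}; expected e.g. '15-19'")


def read_lifetable_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    radix: float | None = None,
) -> AbridgedLifeTable:
    """Load and validate an abridged life table (all type invariants checked)."""
    df, meta = _read_table(path, _AGE_COLS + ["lx", "Lx"], column_map)
    radix = radix if radix is not None else float(meta.get("radix", 100_000))
    lx_end = float(meta["lx_end"]) if "lx_end" in meta else None
    try:
        return AbridgedLifeTable(
            _grid_from(df),
            df["lx"].to_numpy(float),
            df["Lx"].to_numpy(float),
            radix,
            lx_end,
        )
    except InputError as err:
        raise InputError(f"{path}: {err}") from err


def write_lifetable_csv(lt: AbridgedLifeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# radix: {lt.radix:.10g}\n")
        if lt.lx_end is not None:
            fh.write(f"# lx_end: {float(lt.lx_end):.12g}\n")
        pd.DataFrame(
            {
                "age_start": lt.grid.start_ages,
                "age_interval": lt.grid.interval_lengths,
                "lx": lt.lx,
                "Lx": lt.Lx,
            }
        ).to_csv(fh, index=False, float_format="%.10g")


def read_fertility_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    units: str | None = None,
) -> FertilitySchedule:
    df, meta = _read_table(path, _AGE_COLS + ["asfr"], column_map)
    units = units or meta.get("units", "per_woman")
    if units not in RATE_UNITS:
        raise InputError(f"{path}: unknown fertility units {units!r}; use one of {sorted(RATE_UNITS)}")
    try:
        return FertilitySchedule.from_rates(df["asfr"].to_numpy(float), _grid_from(df), units)
    except InputError as err:
        raise InputError(f"{path}: {err}") from err


def write_fertility_csv(fert: FertilitySchedule, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# units: per_woman\n")
        pd.DataFrame(
            {
                "age_start": fert.grid.start_ages,
                "age_interval": fert.grid.interval_lengths,
                "asfr": fert.rates,
            }
        ).to_csv(fh, index=False, float_format="%.12g")


def read_morbidity_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    units: str | None = None,
    event_kind: str = "mnm",
) -> MorbiditySchedule:
    df, meta = _read_table(path, _AGE_COLS, column_map)
    units = units or meta.get("units", "per_birth")
    event_kind = meta.get("event_kind", event_kind)
    grid = _grid_from(df)
    try:
        if {"cases", "live_births"} <= set(df.columns):
            if "ratio" in df.columns:
                return MorbiditySchedule(
                    grid,
                    df["ratio"].to_numpy(float) * RATIO_UNITS[units],
                    df["cases"].to_numpy(float),
                    df["live_births"].to_numpy(float),
                    event_kind,  # type: ignore[arg-type]
                )
            return MorbiditySchedule.from_counts(
                df["cases"].to_numpy(float),
                df["live_births"].to_numpy(float),
                grid,
                event_kind,  # type: ignore[arg-type]
            )
        if "ratio" in df.columns:
            return MorbiditySchedule.from_ratios(
                df["ratio"].to_numpy(float), grid, units, event_kind  # type: ignore[arg-type]
            )
    except InputError as err:
        raise InputError(f"{path}: {err}") from err
    raise InputError(
        f"{path}: need either 'cases' and 'live_births' columns or a 'ratio' column"
    )


def write_morbidity_csv(morb: MorbiditySchedule, path: str | Path) -> None:
    cols = {
        "age_start": morb.grid.start_ages,
        "age_interval": morb.grid.interval_lengths,
    }
    if morb.cases is not None and morb.live_births is not None:
        cols["cases"] = morb.cases
        cols["live_births"] = morb.live_births
    cols["ratio"] = morb.ratio
    with open(path, "w") as fh:
        fh.write("# units: per_birth\n")
        fh.write(f"# event_kind: {morb.event_kind}\n")
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.12g")


def lifetable_to_frame(lt: AbridgedLifeTable) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age_start": lt.grid.start_ages,
            "age_interval": lt.grid.interval_lengths,
            "lx": lt.lx,
            "Lx": lt.Lx,
        }
    )
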