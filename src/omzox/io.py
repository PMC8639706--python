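"""Delimited-text schemas for bottle and profile tables.

Two on-disk tables, both plain CSV with documented headers and units in
the column-name suffixes:

* **bottle time series** — canonical long format, one row per bottle per
  reading: ``bottle_id, time_h, DO_nM[, censored]``. A wide dialect with
  repeated reading columns named ``DO_nM_<hours>h`` (e.g. ``DO_nM_0h,
  DO_nM_12.5h, DO_nM_24h``) is accepted on read only.
* **bottle endpoints** — one row per bottle: identifiers, incubation
  length, pool concentrations, and atom-percent fields; an optional
  ``substitute_for`` column names another bottle whose measurements this
  row replaces (a data-curation directive, applied by the pipeline).
* **profiles** — one row per station x depth with DO, nitrite,
  chlorophyll and optionally the dual nitrate-isotope deltas.

Unknown columns are preserved on round-trip; a missing required column
fails fast naming the column.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .oxygen import OxygenTimeSeries

__all__ = [
    "TIMESERIES_REQUIRED",
    "ENDPOINTS_REQUIRED",
    "PROFILE_REQUIRED",
    "read_timeseries",
    "write_timeseries",
    "read_endpoints",
    "write_endpoints",
    "read_profiles",
    "write_profiles",
    "timeseries_to_oxygen",
]

TIMESERIES_REQUIRED = ("bottle_id", "time_h", "DO_nM")
ENDPOINTS_REQUIRED = ("bottle_id", "treatment", "t_hours")
PROFILE_REQUIRED = ("station", "depth_m", "DO_nM", "NO2_nM", "chl_mg_m3")

_WIDE_DO = re.compile(r"^DO_nM_([0-9]+(?:\.[0-9]+)?)h$")


class SchemaError(ValueError):
    """A required column is missing or a row failed to parse."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{what} table is missing required column(s): {', '.join(missing)}"
        )


def _read_csv(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    try:
        return pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:  # surface the row number pandas reports
        raise SchemaError(f"{what} table failed to parse: {exc}") from exc


def read_timeseries(path: str | Path) -> pd.DataFrame:
    """Read DO readings in long or wide dialect; returns long format."""
    df = _read_csv(path, "time-series")
    wide_cols = [c for c in df.columns if _WIDE_DO.match(c)]
    if wide_cols and "DO_nM" not in df.columns:
        if "bottle_id" not in df.columns:
            raise SchemaError(
                "time-series table is missing required column(s): bottle_id"
            )
        records = []
        for _, row in df.iterrows():
            for col in wide_cols:
                t = float(_WIDE_DO.match(col).group(1))
                records.append(
                    {
                        "bottle_id": row["bottle_id"],
                        "time_h": t,
                        "DO_nM": row[col],
                        "censored": bool(row.get(f"censored_{t:g}h", False)),
                    }
                )
        df = pd.DataFrame.from_records(records)
    _check_columns(df, TIMESERIES_REQUIRED, "time-series")
    if "censored" not in df.columns:
        df["censored"] = False
    df = df.sort_values(["bottle_id", "time_h"], kind="mergesort").reset_index(drop=True)
    return df


def write_timeseries(df: pd.DataFrame, path: str | Path) -> None:
    _check_columns(df, TIMESERIES_REQUIRED, "time-series")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def timeseries_to_oxygen(
    df: pd.DataFrame, detection_limit: float = 10.0
) -> dict[str, OxygenTimeSeries]:
    """Group a long-format reading table into per-bottle series."""
    out: dict[str, OxygenTimeSeries] = {}
    for bid, grp in df.groupby("bottle_id", sort=False):
        grp = grp.sort_values("time_h")
        out[str(bid)] = OxygenTimeSeries(
            bottle_id=str(bid),
            times=grp["time_h"].to_numpy(dtype=float),
            DO=grp["DO_nM"].to_numpy(dtype=float),
            censored=grp["censored"].to_numpy(dtype=bool)
            if "censored" in grp.columns
            else None,
            sensor_detection_limit=detection_limit,
        )
    return out


def read_endpoints(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, "endpoints")
    _check_columns(df, ENDPOINTS_REQUIRED, "endpoints")
    return df


def write_endpoints(df: pd.DataFrame, path: str | Path) -> None:
    _check_columns(df, ENDPOINTS_REQUIRED, "endpoints")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def apply_substitutions(endpoints: pd.DataFrame) -> pd.DataFrame:
    """Apply ``substitute_for`` directives: a row naming another bottle
    replaces that bottle's measurements (the donor row is dropped)."""
    if "substitute_for" not in endpoints.columns:
        return endpoints
    df = endpoints.copy()
    subs = df[df["substitute_for"].notna() & (df["substitute_for"] != "")]
    for _, row in subs.iterrows():
        target = row["substitute_for"]
        df = df[df["bottle_id"] != target]
    df = df.drop(columns=["substitute_for"])
    return df.reset_index(drop=True)


def read_profiles(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, "profile")
    _check_columns(df, PROFILE_REQUIRED, "profile")
    return df


def write_profiles(df: pd.DataFrame, path: str | Path) -> None:
    _check_columns(df, PROFILE_REQUIRED, "profile")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
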