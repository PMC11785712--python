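"""Readers and writers for the interchange formats.

Station weather and vintage tables travel as UTF-8 comma-separated CSV with
ISO-8601 dates; teleconnection indices as CPC-style whitespace text (one row
per year, twelve monthly columns); gridded fields as NetCDF (classic format
via the scipy backend); vineyard fractions as a small CSV.  Readers validate
the domain invariants and report offending rows by line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import bioclim

__all__ = [
    "ParseError",
    "read_station_csv", "write_station_csv",
    "read_vintage_csv", "write_vintage_csv",
    "read_index_table", "write_index_table",
    "read_netcdf_grid", "write_netcdf_grid",
    "read_fraction_table", "write_fraction_table",
    "read_spei_csv", "write_spei_csv",
]


class ParseError(ValueError):
    """A file violated the expected schema; the message names the spot."""


STATION_COLUMNS = ("tx", "tn", "pp", "ss", "cc", "hr")


def read_station_csv(path) -> pd.DataFrame:
    """Daily station CSV (date,tx,tn,pp,ss,cc,hr) -> validated daily frame."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if "date" not in df.columns:
        raise ParseError(f"{path}: missing 'date' column")
    for col in ("tx", "tn", "pp"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    try:
        idx = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: unparseable ISO date ({exc})") from exc
    out = df.drop(columns=["date"]).set_index(idx)
    bad = out["tx"] < out["tn"]
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ParseError(f"{path}: TX < TN at line {row}")
    try:
        return bioclim.validate_daily(out)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_station_csv(daily: pd.DataFrame, path) -> None:
    out = daily.copy()
    out.insert(0, "date", daily.index.strftime("%Y-%m-%d"))
    out.to_csv(path, index=False, float_format="%.6g")


def read_vintage_csv(path) -> pd.DataFrame:
    """Vintage CSV (year + variables) -> table indexed by year."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if "year" not in df.columns:
        raise ParseError(f"{path}: missing 'year' column")
    df = df.set_index("year")
    for col in ("veraison_doy", "harvest_doy"):
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < 1) | (vals > 366)).any():
                raise ParseError(f"{path}: {col} outside [1, 366]")
    if "rating" in df.columns:
        df["rating"] = pd.Categorical(
            df["rating"], categories=["good", "very good", "excellent"], ordered=True
        )
    return df


def write_vintage_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, float_format="%.6g")


def read_index_table(path) -> pd.DataFrame:
    """CPC-style teleconnection text -> (year, month)-indexed table.

    The format is blocks introduced by ``# <mode>`` lines, each row then
    ``year v1 .. v12`` whitespace-separated.  A single unlabelled block is
    read as one unnamed index.
    """
    path = Path(path)
    blocks: dict[str, dict[int, list[float]]] = {}
    current = "index"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                current = line.lstrip("#").strip().lower() or current
                continue
            parts = line.split()
            if len(parts) != 13:
                raise ParseError(f"{path}: line {lineno}: expected year + 12 values, "
                                 f"got {len(parts)} fields")
            try:
                year = int(parts[0])
                values = [float(v) for v in parts[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            blocks.setdefault(current, {})[year] = values
    if not blocks:
        raise ParseError(f"{path}: no data rows")
    frames = {}
    for mode, rows in blocks.items():
        years = sorted(rows)
        idx = pd.MultiIndex.from_product([years, range(1, 13)], names=["year", "month"])
        frames[mode] = pd.Series(
            np.concatenate([rows[y] for y in years]), index=idx
        )
    return pd.DataFrame(frames)


def write_index_table(table: pd.DataFrame, path) -> None:
    """Write a (year, month)-indexed table as CPC-style blocks."""
    with open(path, "w") as fh:
        for mode in table.columns:
            fh.write(f"# {mode}\n")
            wide = table[mode].unstack("month")
            for year, row in wide.iterrows():
                vals = " ".join(f"{v:8.3f}" for v in row.to_numpy())
                fh.write(f"{int(year)} {vals}\n")


def read_netcdf_grid(path) -> xr.Dataset:
    """NetCDF grid (classic format) with lat/lon/time axes."""
    ds = xr.open_dataset(path, engine="scipy")
    for axis in ("time", "lat", "lon"):
        if axis not in ds.coords:
            raise ParseError(f"{path}: missing coordinate {axis!r}")
        vals = ds[axis].values
        if axis != "time" and len(vals) > 1 and not (np.all(np.diff(vals) > 0)
                                                     or np.all(np.diff(vals) < 0)):
            raise ParseError(f"{path}: coordinate {axis!r} is not monotone")
    return ds.load()


def write_netcdf_grid(ds: xr.Dataset, path) -> None:
    ds.to_netcdf(path, engine="scipy", format="NETCDF3_CLASSIC")


def read_fraction_table(path) -> pd.DataFrame:
    """Per-pixel vineyard-fraction CSV (pixel, lat, lon, fraction)."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in ("pixel", "lat", "lon", "fraction"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    bad = (df["fraction"] < 0) | (df["fraction"] > 1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ParseError(f"{path}: fraction outside [0, 1] at line {row}")
    return df


def write_fraction_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.6g")


def read_spei_csv(path) -> pd.Series:
    """Monthly SPEI CSV (year, month, spei) -> (year, month)-indexed Series."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in ("year", "month", "spei"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return df.set_index(["year", "month"])["spei"].astype(float)


def write_spei_csv(series: pd.Series, path) -> None:
    df = series.rename("spei").reset_index()
    df.columns = ["year", "month", "spei"]
    df.to_csv(path, index=False, float_format="%.6g")
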