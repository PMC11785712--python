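"""Gridded diagnostics: vineyard LAI pixel selection, regional phenology
series, seasonal SST windows and correlation maps with analytic significance
masking."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

from . import robust_stats

__all__ = [
    "pixel_area",
    "select_vineyard_pixels",
    "regional_lai_series",
    "annual_cycle_summary",
    "seasonal_sst_mean",
    "correlation_map",
    "EARTH_RADIUS_KM",
    "DEFAULT_LATITUDE",
]

EARTH_RADIUS_KM = 6371.0
DEFAULT_LATITUDE = 42.45  # upper Ebro valley vineyard belt
KM_PER_DEGREE = np.pi * EARTH_RADIUS_KM / 180.0


def pixel_area(resolution_deg: float, latitude: float = DEFAULT_LATITUDE) -> float:
    """Area (km^2) of a square lat-lon pixel of the given angular size.

    ``(resolution * L)^2 * cos(latitude)`` on a spherical Earth with
    L ~ 111.2 km per degree.  At the native 0.0727273-degree resolution this
    gives about 48.3 km^2 at 42.45 N and 65.4 km^2 at the equator.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude outside [-90, 90]")
    side = resolution_deg * KM_PER_DEGREE
    return float(side**2 * np.cos(np.deg2rad(latitude)))


def select_vineyard_pixels(fraction_table: pd.DataFrame, threshold: float = 0.75) -> pd.Series:
    """Boolean mask of pixels with vineyard fraction >= threshold (inclusive).

    The table needs a ``fraction`` column in [0, 1] (and typically ``pixel``,
    ``lat``, ``lon``).  An empty selection warns and returns the all-False
    mask rather than failing.
    """
    frac = fraction_table["fraction"]
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("vineyard fractions must lie in [0, 1]")
    mask = frac >= threshold
    if not mask.any():
        warnings.warn(f"no pixel reaches vineyard fraction {threshold}")
    return mask


def regional_lai_series(grid: xr.Dataset | xr.DataArray, mask: pd.Series | np.ndarray) -> pd.Series:
    """Unweighted mean LAI over the selected pixels, per month.

    ``mask`` is boolean over the flattened (lat, lon) pixel order.  Returns a
    Series indexed by (year, month); empty selections return an empty Series.
    Pixels at one latitude band are near equal-area, so the plain mean is the
    default.
    """
    da = grid["lai"] if isinstance(grid, xr.Dataset) else grid
    mask = np.asarray(mask, dtype=bool)
    nlat, nlon = da.sizes["lat"], da.sizes["lon"]
    if mask.size != nlat * nlon:
        raise ValueError("mask length does not match the pixel count")
    if not mask.any():
        return pd.Series(dtype=float)
    flat = da.values.reshape(da.sizes["time"], -1)
    series = flat[:, mask].mean(axis=1)
    times = pd.DatetimeIndex(da["time"].values)
    idx = pd.MultiIndex.from_arrays([times.year, times.month], names=["year", "month"])
    return pd.Series(series, index=idx)


def annual_cycle_summary(monthly: pd.Series) -> pd.DataFrame:
    """Per-calendar-month mean and standard deviation of a monthly series."""
    grp = monthly.groupby(level="month")
    return pd.DataFrame({"mean": grp.mean(), "std": grp.std(ddof=1)})


def seasonal_sst_mean(
    grid: xr.Dataset | xr.DataArray,
    months: tuple[int, ...] = (12, 1, 2, 3, 4, 5),
) -> pd.DataFrame:
    """Per-pixel mean over a window ending in the labelled year.

    The default previous-December-to-May window attributes December of year
    t-1 and January-May of year t to year t.  Months numbered 12 (or any
    month >= the first in-window month after the wrap) are taken from the
    previous year.  Years whose window is incomplete (e.g. the first year,
    missing its December) are dropped.  Returns year x pixel (flattened
    lat-lon order).
    """
    da = grid["sst"] if isinstance(grid, xr.Dataset) else grid
    times = pd.DatetimeIndex(da["time"].values)
    flat = da.values.reshape(len(times), -1)
    frame = pd.DataFrame(flat, index=pd.MultiIndex.from_arrays(
        [times.year, times.month], names=["year", "month"]))
    wrap = [m for m in months if m >= 7]  # months attributed to the previous year
    rows = {}
    years = sorted(frame.index.get_level_values("year").unique())
    for year in years:
        keys = [((year - 1) if m in wrap else year, m) for m in months]
        if not all(k in frame.index for k in keys):
            continue
        rows[year] = frame.loc[keys].mean(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "year"
    return out


def correlation_map(
    index_series: pd.Series,
    pixel_table: pd.DataFrame,
    detrend: bool = True,
    alpha: float = 0.05,
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Pearson correlation of an annual index with every pixel series.

    Both the index and each pixel series are linearly detrended in year when
    ``detrend`` is set.  Pixels with missing years use their
    pairwise-complete sample, and each pixel's significance threshold is the
    critical r for its own n.  Returns ``(r, significant, threshold)``
    Series over pixels.
    """
    idx = pd.Series(index_series).astype(float)
    common = idx.index.intersection(pixel_table.index)
    if len(common) < 4:
        raise ValueError("need at least 4 overlapping years")
    idx = idx.loc[common]
    pix = pixel_table.loc[common]

    r_vals, sig, thr = {}, {}, {}
    years_all = np.asarray(common, dtype=float)
    for col in pix.columns:
        y = pix[col].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(idx.to_numpy())
        n = int(ok.sum())
        if n < 4:
            r_vals[col], sig[col], thr[col] = np.nan, False, np.nan
            continue
        xv = idx.to_numpy()[ok]
        yv = y[ok]
        t = years_all[ok]
        if detrend:
            xv = xv - np.polyval(np.polyfit(t, xv, 1), t)
            yv = yv - np.polyval(np.polyfit(t, yv, 1), t)
        xc = xv - xv.mean()
        yc = yv - yv.mean()
        denom = np.sqrt((xc @ xc) * (yc @ yc))
        r = float(xc @ yc / denom) if denom > 0 else np.nan
        rc = robust_stats.critical_r(n, alpha)
        r_vals[col] = r
        thr[col] = rc
        sig[col] = bool(np.isfinite(r) and abs(r) >= rc)
    return (
        pd.Series(r_vals, name="r"),
        pd.Series(sig, name="significant"),
        pd.Series(thr, name="critical_r"),
    )
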