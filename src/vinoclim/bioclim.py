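"""Viticultural bioclimatic indices from daily station data.

A daily station record (TX, TN, PP, SS, CC, HR) is turned into monthly
aggregates, threshold day counts (hot, frost and wet days), and the four
classical grape-growing indices: Growing Degree Days (GDD), the Huglin
heliothermal index (HI), the Cool Night Index (CI) and the Dryness Index
(DI).  SPEI values are consumed from an external product and only windowed
here, never fitted.

Daily data are held in a pandas DataFrame with a DatetimeIndex and columns
``tx, tn, pp, ss, cc, hr`` (degC, degC, mm/day, h/day, oktas or fraction, %).
"""

from __future__ import annotations

import calendar
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "validate_daily",
    "aggregate_monthly",
    "count_days",
    "growing_degree_days",
    "huglin_index",
    "huglin_k",
    "cool_night_index",
    "thornthwaite_pet",
    "dryness_index",
    "spei_windows",
    "bioclim_table",
    "GROWING_SEASON",
    "HD_THRESHOLD",
    "FD_THRESHOLD",
    "WD_THRESHOLD",
]

GROWING_SEASON = (4, 10)  # April-October, inclusive
HD_THRESHOLD = 30.0  # hot day: TX strictly above, degC
FD_THRESHOLD = 0.0  # frost day: TN strictly below, degC
WD_THRESHOLD = 1.0  # wet day: PP strictly above, mm

REQUIRED_COLUMNS = ("tx", "tn", "pp")


def validate_daily(daily: pd.DataFrame) -> pd.DataFrame:
    """Check the structural invariants of a daily weather frame.

    Raises ``ValueError`` if dates are not strictly increasing and gap-free,
    if TX < TN anywhere, if precipitation is negative, or if relative
    humidity leaves [0, 100].
    """
    if not isinstance(daily.index, pd.DatetimeIndex):
        raise ValueError("daily weather requires a DatetimeIndex")
    for col in REQUIRED_COLUMNS:
        if col not in daily.columns:
            raise ValueError(f"missing required column {col!r}")
    idx = daily.index
    if len(idx) > 1:
        deltas = np.diff(idx.values).astype("timedelta64[D]").astype(int)
        if (deltas <= 0).any():
            raise ValueError("dates must be strictly increasing")
        if (deltas != 1).any():
            raise ValueError("daily series has gaps within its coverage")
    bad = daily["tx"] < daily["tn"]
    if bad.any():
        day = daily.index[bad.to_numpy().argmax()].date()
        raise ValueError(f"TX < TN on {day}")
    if (daily["pp"] < 0).any():
        raise ValueError("negative precipitation")
    if "hr" in daily.columns and ((daily["hr"] < 0) | (daily["hr"] > 100)).any():
        raise ValueError("relative humidity outside [0, 100]")
    return daily


def _year_window(daily: pd.DataFrame, year: int, months: tuple[int, int]) -> pd.DataFrame:
    m0, m1 = months
    sel = (daily.index.year == year) & (daily.index.month >= m0) & (daily.index.month <= m1)
    return daily.loc[sel]


def _window_days(year: int, months: tuple[int, int]) -> int:
    return sum(calendar.monthrange(year, m)[1] for m in range(months[0], months[1] + 1))


def aggregate_monthly(daily: pd.DataFrame, allow_partial: bool = False) -> pd.DataFrame:
    """Monthly means of TX/TN/CC/HR/SS (plus an SS sum) and PP totals.

    Partial months are excluded with a warning unless ``allow_partial``.
    The result is indexed by (year, month).
    """
    validate_daily(daily)
    grouper = [daily.index.year.rename("year"), daily.index.month.rename("month")]
    counts = daily.groupby(grouper).size()
    out = pd.DataFrame(index=counts.index)
    for col in ("tx", "tn", "cc", "hr", "ss"):
        if col in daily.columns:
            out[col] = daily[col].groupby(grouper).mean()
    if "ss" in daily.columns:
        out["ss_total"] = daily["ss"].groupby(grouper).sum()
    out["pp_total"] = daily["pp"].groupby(grouper).sum()

    full = counts.index.map(lambda ym: calendar.monthrange(ym[0], ym[1])[1])
    partial = counts < pd.Series(full, index=counts.index)
    if partial.any() and not allow_partial:
        dropped = list(counts.index[partial])
        warnings.warn(f"excluding {len(dropped)} partial month(s): {dropped}")
        out = out.loc[~partial]
    out.index = out.index.set_names(["year", "month"])
    return out


_PREDICATES = {
    "HD": lambda d: d["tx"] > HD_THRESHOLD,
    "FD": lambda d: d["tn"] < FD_THRESHOLD,
    "WD": lambda d: d["pp"] > WD_THRESHOLD,
}


def count_days(
    daily: pd.DataFrame,
    year: int,
    predicate: str,
    months: tuple[int, int] = GROWING_SEASON,
) -> int:
    """Count hot (TX > 30), frost (TN < 0) or wet (PP > 1 mm) days in a window.

    Inequalities are strict, so a day with TX exactly 30.0 degC is not hot and
    a day with exactly 1 mm is not wet.
    """
    if predicate not in _PREDICATES:
        raise ValueError(f"unknown predicate {predicate!r}; use one of {sorted(_PREDICATES)}")
    window = _year_window(validate_daily(daily), year, months)
    if window.empty:
        raise ValueError(f"no data for {year} months {months}")
    return int(_PREDICATES[predicate](window).sum())


def _require_full_window(window: pd.DataFrame, year: int, months: tuple[int, int],
                         allow_partial: bool, what: str) -> None:
    expected = _window_days(year, months)
    if len(window) != expected and not allow_partial:
        raise ValueError(
            f"{what}: window {months} of {year} has {len(window)} days, expected {expected}"
        )


def growing_degree_days(
    daily: pd.DataFrame,
    year: int,
    months: tuple[int, int] = GROWING_SEASON,
    base: float = 10.0,
    allow_partial: bool = False,
) -> float:
    """GDD: sum of max(0, (TX+TN)/2 - base) over the growing season."""
    window = _year_window(validate_daily(daily), year, months)
    _require_full_window(window, year, months, allow_partial, "GDD")
    tmean = (window["tx"] + window["tn"]) / 2.0
    return float(np.maximum(tmean - base, 0.0).sum())


# Huglin day-length coefficient K versus |latitude|; interpolated linearly
# between rows, clamped outside the table.
_HUGLIN_TABLE = np.array(
    [[40.0, 1.02], [42.0, 1.03], [44.0, 1.04], [46.0, 1.05], [48.0, 1.06], [50.0, 1.06]]
)


def huglin_k(latitude: float) -> float:
    """Day-length coefficient for the Huglin index at a latitude (degrees)."""
    if not -60.0 <= latitude <= 60.0:
        raise ValueError("latitude outside [-60, 60]")
    return float(np.interp(abs(latitude), _HUGLIN_TABLE[:, 0], _HUGLIN_TABLE[:, 1]))


def huglin_index(
    daily: pd.DataFrame,
    latitude: float,
    year: int,
    months: tuple[int, int] = (4, 9),
    allow_partial: bool = False,
) -> float:
    """Huglin heliothermal index over April-September.

    ``HI = sum K * max(0, ((Tmean - 10) + (TX - 10)) / 2)`` with
    ``Tmean = (TX + TN)/2`` and K the latitude-dependent day-length factor.
    """
    k = huglin_k(latitude)
    window = _year_window(validate_daily(daily), year, months)
    _require_full_window(window, year, months, allow_partial, "HI")
    tmean = (window["tx"] + window["tn"]) / 2.0
    daily_term = np.maximum(((tmean - 10.0) + (window["tx"] - 10.0)) / 2.0, 0.0)
    return float(k * daily_term.sum())


def cool_night_index(daily: pd.DataFrame, year: int, allow_partial: bool = False) -> float:
    """Cool Night Index: mean September minimum temperature (degC)."""
    window = _year_window(validate_daily(daily), year, (9, 9))
    _require_full_window(window, year, (9, 9), allow_partial, "CI")
    return float(window["tn"].mean())


def _day_length_hours(latitude: float, doy: np.ndarray) -> np.ndarray:
    """Mean astronomical day length (h) by day of year, standard solar geometry."""
    phi = np.deg2rad(latitude)
    decl = 0.409 * np.sin(2 * np.pi / 365.0 * doy - 1.39)
    cos_omega = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    omega = np.arccos(cos_omega)
    return 24.0 / np.pi * omega


def thornthwaite_pet(monthly_tmean: Mapping[int, float], latitude: float, year: int) -> dict[int, float]:
    """Thornthwaite monthly potential evapotranspiration (mm/month).

    ``PET = 16 (L/12)(N/30)(10 T / I)^a`` for T > 0 (else 0), with the annual
    heat index ``I = sum (T_i/5)^1.514`` over months with positive mean
    temperature, the cubic exponent ``a(I)``, month length N and mean day
    length L at the given latitude.  Needs only monthly mean temperature, so
    it is the default PET supply for the Dryness Index; any mapping of
    month -> PET may be substituted.
    """
    temps = {m: float(t) for m, t in monthly_tmean.items()}
    heat = sum((t / 5.0) ** 1.514 for t in temps.values() if t > 0)
    if heat <= 0:
        return {m: 0.0 for m in temps}
    a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
    pet = {}
    for m, t in temps.items():
        if t <= 0:
            pet[m] = 0.0
            continue
        n_days = calendar.monthrange(year, m)[1]
        mid = sum(calendar.monthrange(year, mm)[1] for mm in range(1, m)) + n_days / 2.0
        day_len = float(_day_length_hours(latitude, np.array([mid]))[0])
        pet[m] = 16.0 * (day_len / 12.0) * (n_days / 30.0) * (10.0 * t / heat) ** a
    return pet


_DI_K = {4: 0.1, 5: 0.3, 6: 0.5, 7: 0.5, 8: 0.5, 9: 0.5}


def dryness_index(
    monthly_p: Mapping[int, float],
    monthly_pet: Mapping[int, float],
    monthly_wet_days: Mapping[int, float] | None = None,
    year: int = 2001,
    w0: float = 200.0,
) -> float:
    """Dryness Index: potential soil-water reserve at the end of September.

    Runs the monthly balance ``W <- min(W0, W + P - Tv - Es)`` from April to
    September with initial reserve ``W0`` (200 mm), vine transpiration
    ``Tv = k * PET`` (k = 0.1 in April, 0.3 in May, 0.5 June-September) and
    bare-soil evaporation ``Es = PET/N * (1 - k) * JPm`` where N is the days
    in the month and JPm = min(N/5, wet-day count) approximates the days of
    effective soil evaporation.  W is capped above at W0 but may go negative.

    ``monthly_wet_days`` defaults to N/5 each month when not supplied.
    """
    months = range(4, 10)
    for m in months:
        if m not in monthly_p or m not in monthly_pet:
            raise ValueError(f"month {m} missing from P or PET inputs")
        if monthly_pet[m] < 0:
            raise ValueError("PET must be non-negative")
    w = w0
    for m in months:
        n_days = calendar.monthrange(year, m)[1]
        k = _DI_K[m]
        jpm = n_days / 5.0
        if monthly_wet_days is not None:
            jpm = min(jpm, float(monthly_wet_days.get(m, jpm)))
        tv = k * monthly_pet[m]
        es = monthly_pet[m] / n_days * (1.0 - k) * jpm
        w = min(w0, w + monthly_p[m] - tv - es)
    return float(w)


# SPEI windows, as (start (year offset, month), end (year offset, month)),
# both inclusive; offset -1 means the previous calendar year.
SPEI_WINDOWS = {
    "spei3": ((0, 7), (0, 9)),   # July-September: summer
    "spei6": ((0, 3), (0, 9)),   # March-September: growing season (7 months
                                 # despite the conventional "6" label)
    "spei12": ((-1, 10), (0, 9)),  # previous October-September
}


def spei_windows(monthly_spei: pd.Series, year: int) -> dict[str, float]:
    """Windowed means of an external monthly SPEI series for one vintage year.

    ``monthly_spei`` is indexed by (year, month).  Returns means over
    July-September (summer), March-September (growing season) and previous
    October-September (hydrological year).  Missing months raise KeyError.
    """
    out = {}
    for name, ((oy0, m0), (oy1, m1)) in SPEI_WINDOWS.items():
        start = (year + oy0) * 12 + (m0 - 1)
        end = (year + oy1) * 12 + (m1 - 1)
        values = [monthly_spei.loc[(k // 12, k % 12 + 1)] for k in range(start, end + 1)]
        out[name] = float(np.mean(values))
    return out


def bioclim_table(
    daily: pd.DataFrame,
    latitude: float,
    monthly_spei: pd.Series | None = None,
    pet_func=thornthwaite_pet,
) -> pd.DataFrame:
    """Annual table of all bioclimatic indices for every complete year.

    One row per year with GDD, HI, CI, DI, HD/FD/WD counts over the growing
    season, total April-October precipitation, and (when a SPEI series is
    supplied) the three SPEI windows.
    """
    validate_daily(daily)
    monthly = aggregate_monthly(daily, allow_partial=True)
    rows = []
    for year in sorted(set(daily.index.year)):
        ydays = daily.loc[daily.index.year == year]
        if len(ydays) < (366 if calendar.isleap(year) else 365):
            continue
        tmean_m = {
            m: float((monthly.loc[(year, m), "tx"] + monthly.loc[(year, m), "tn"]) / 2.0)
            for m in range(1, 13)
        }
        pet = pet_func(tmean_m, latitude, year)
        p_m = {m: float(monthly.loc[(year, m), "pp_total"]) for m in range(4, 10)}
        wet = {m: count_days(daily, year, "WD", (m, m)) for m in range(4, 10)}
        row = {
            "year": year,
            "gdd": growing_degree_days(daily, year),
            "hi": huglin_index(daily, latitude, year),
            "ci": cool_night_index(daily, year),
            "di": dryness_index(p_m, {m: pet[m] for m in range(4, 10)}, wet, year),
            "hd": count_days(daily, year, "HD"),
            "fd": count_days(daily, year, "FD"),
            "wd": count_days(daily, year, "WD"),
            "pp_total": float(
                sum(monthly.loc[(year, m), "pp_total"] for m in range(4, 11))
            ),
        }
        if monthly_spei is not None:
            try:
                row.update(spei_windows(monthly_spei, year))
            except KeyError:
                pass  # incomplete SPEI coverage for this year
        rows.append(row)
    return pd.DataFrame(rows).set_index("year")
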