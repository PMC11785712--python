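"""Tercile-composite anomaly analysis with bootstrap significance envelopes.

The core diagnostic of the pipeline: a monthly variable is detrended per
calendar month, an annual index (typically a PC score series) is detrended
and split into terciles, and the mean monthly residual anomaly over the
high- and low-tercile years is compared against a resampling envelope (5th
and 95th percentiles of 10,000 composites of randomly drawn year sets of the
same size).  A month is flagged when its composite falls outside that
envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TerciledSeries",
    "CompositeResult",
    "detrend_monthly",
    "classify_terciles",
    "composite_anomalies",
    "bootstrap_envelope",
    "composite_report",
]

log = logging.getLogger(__name__)


def _monthly_series(series) -> pd.Series:
    """Coerce input to a float Series indexed by (year, month)."""
    s = pd.Series(series).astype(float)
    if not isinstance(s.index, pd.MultiIndex) or s.index.nlevels != 2:
        raise ValueError("monthly series must be indexed by (year, month)")
    s.index = s.index.set_names(["year", "month"])
    return s


def detrend_monthly(monthly: pd.Series, min_years: int = 4) -> pd.Series:
    """Remove a per-calendar-month linear trend in year; return residuals.

    Each calendar month gets its own least-squares line in year, fitted and
    subtracted independently, so a trend confined to (say) May never leaks
    into other months' residuals.  Months observed in fewer than
    ``min_years`` years are excluded with a warning.
    """
    s = _monthly_series(monthly)
    pieces = []
    for month, grp in s.groupby(level="month"):
        years = grp.index.get_level_values("year").to_numpy(dtype=float)
        if len(grp) < min_years:
            log.warning("month %s has %d year(s) < %d; excluded", month, len(grp), min_years)
            continue
        coeffs = np.polyfit(years, grp.to_numpy(), 1)
        pieces.append(grp - np.polyval(coeffs, years))
    if not pieces:
        raise ValueError("no calendar month has enough years to detrend")
    return pd.concat(pieces).sort_index()


def _detrend_annual(values: np.ndarray, years: np.ndarray) -> np.ndarray:
    coeffs = np.polyfit(years, values, 1)
    return values - np.polyval(coeffs, years)


@dataclass
class TerciledSeries:
    """Tercile classification of an annual index series.

    ``low_years``/``high_years`` each hold the ``m = floor(n/3)`` most
    extreme years of the (optionally detrended) index; all other years are
    labelled ``mid``.
    """

    values: pd.Series
    detrended: pd.Series
    labels: pd.Series  # year -> {"low", "mid", "high"}
    low_years: tuple
    high_years: tuple
    m: int


def classify_terciles(index_series: pd.Series, detrend: bool = True) -> TerciledSeries:
    """Split an annual index into low/mid/high terciles after detrending.

    Ties straddling a tercile boundary are broken by year order: the earlier
    year enters the extreme set (logged).  For a 25-year series each extreme
    set holds exactly 8 years.
    """
    s = pd.Series(index_series).astype(float).sort_index()
    n = len(s)
    if n < 6:
        raise ValueError(f"need at least 6 years, got {n}")
    years = np.asarray(s.index, dtype=float)
    vals = s.to_numpy()
    resid = _detrend_annual(vals, years) if detrend else vals.copy()
    detrended = pd.Series(resid, index=s.index)

    m = n // 3
    order = np.lexsort((np.arange(n), resid))  # ascending value, then year order
    low = s.index[order[:m]]
    order_desc = np.lexsort((np.arange(n), -resid))
    high = s.index[order_desc[:m]]
    if len(np.unique(resid)) < n:
        log.info("ties present; boundary ties broken by year order")
    labels = pd.Series("mid", index=s.index)
    labels.loc[low] = "low"
    labels.loc[high] = "high"
    return TerciledSeries(
        values=s,
        detrended=detrended,
        labels=labels,
        low_years=tuple(low),
        high_years=tuple(high),
        m=m,
    )


def composite_anomalies(residuals: pd.Series, year_set) -> pd.Series:
    """Per-calendar-month mean residual over a set of years."""
    s = _monthly_series(residuals)
    year_set = set(year_set)
    sel = s[s.index.get_level_values("year").isin(year_set)]
    if sel.empty:
        raise ValueError("year set has no overlap with the residual series")
    return sel.groupby(level="month").mean()


def _residual_matrix(residuals: pd.Series) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    s = _monthly_series(residuals)
    wide = s.unstack("month")
    return wide.to_numpy(), wide.index.to_numpy(), wide.columns.to_numpy()


def bootstrap_envelope(
    residuals: pd.Series,
    m: int,
    n_boot: int = 10_000,
    percentiles: tuple[float, float] = (5.0, 95.0),
    seed: int = 0,
    replace: bool = True,
) -> pd.DataFrame:
    """Bootstrap envelope for m-year composite means, per calendar month.

    Each replicate draws one set of ``m`` years (with replacement by default;
    ``replace=False`` gives without-replacement subsampling) and that same
    draw is reused for every calendar month, preserving cross-month
    dependence.  Returns a DataFrame indexed by month with columns
    ``lo``/``hi`` at the requested percentiles.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    mat, years, months = _residual_matrix(residuals)
    n_years = len(years)
    if m > n_years and not replace:
        raise ValueError(f"cannot subsample {m} from {n_years} years without replacement")
    rng = np.random.default_rng(seed)
    if replace:
        draws = rng.integers(0, n_years, size=(n_boot, m))
    else:
        draws = np.array([rng.choice(n_years, size=m, replace=False) for _ in range(n_boot)])
    rep_means = np.nanmean(mat[draws], axis=1)  # (n_boot, n_months)
    lo, hi = np.nanpercentile(rep_means, percentiles, axis=0)
    return pd.DataFrame({"lo": lo, "hi": hi}, index=pd.Index(months, name="month"))


@dataclass
class CompositeResult:
    """Composite anomalies for both extreme categories with their envelopes.

    ``composites`` has one column per category ("high", "low"); ``envelope``
    the per-month lo/hi bootstrap thresholds; ``flags`` is True where a
    composite falls strictly outside the envelope.
    """

    composites: pd.DataFrame
    envelope: pd.DataFrame
    flags: pd.DataFrame
    terciles: TerciledSeries
    n_boot: int
    percentiles: tuple[float, float]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy (month, category, composite, lo, hi, significant) table."""
        rows = []
        for cat in self.composites.columns:
            for month in self.composites.index:
                rows.append({
                    "month": int(month),
                    "category": cat,
                    "composite": self.composites.loc[month, cat],
                    "lo": self.envelope.loc[month, "lo"],
                    "hi": self.envelope.loc[month, "hi"],
                    "significant": bool(self.flags.loc[month, cat]),
                })
        return pd.DataFrame(rows)


def composite_report(
    monthly: pd.Series,
    index_series: pd.Series,
    n_boot: int = 10_000,
    percentiles: tuple[float, float] = (5.0, 95.0),
    seed: int = 0,
    detrend_index: bool = True,
    replace: bool = True,
) -> CompositeResult:
    """Full composite analysis of one monthly variable against an annual index.

    Orchestrates: per-month detrending of the variable, tercile
    classification of the (detrended) index, high/low composite anomalies,
    and the bootstrap envelope; months are flagged significant when the
    composite lies outside the envelope.  Applies identically to station
    variables, regional LAI series and teleconnection indices.
    """
    residuals = detrend_monthly(monthly)
    terc = classify_terciles(index_series, detrend=detrend_index)
    high = composite_anomalies(residuals, terc.high_years)
    low = composite_anomalies(residuals, terc.low_years)
    composites = pd.DataFrame({"high": high, "low": low})
    envelope = bootstrap_envelope(
        residuals, terc.m, n_boot=n_boot, percentiles=percentiles, seed=seed,
        replace=replace,
    )
    envelope = envelope.reindex(composites.index)
    flags = pd.DataFrame({
        cat: (composites[cat] < envelope["lo"]) | (composites[cat] > envelope["hi"])
        for cat in composites.columns
    })
    return CompositeResult(
        composites=composites,
        envelope=envelope,
        flags=flags,
        terciles=terc,
        n_boot=n_boot,
        percentiles=percentiles,
        seed=seed,
    )
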