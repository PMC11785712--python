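"""Synthetic inputs with known ground-truth couplings.

The real vintage records this pipeline was designed around are confidential,
so every downstream stage is exercised against generated data whose causal
structure is known exactly:

* daily station weather for a Mediterranean-continental site (sinusoidal
  seasonal cycles + AR(1) residual, two-state Markov/gamma precipitation with
  spring and autumn maxima, an imposed linear warming trend);
* an annual vintage table whose chemistry and phenology respond linearly to
  standardized May-July maximum-temperature anomalies and to growing-season
  wetness, with configurable slopes and noise;
* a monthly LAI grid whose summer canopy is negatively coupled to summer
  heat, plus a per-pixel vineyard-fraction table;
* four standardized AR(1) monthly teleconnection indices (NAO, EA, EA/WR,
  SCAND) with an optional imposed May EA - May TX coupling;
* a gridded SST field equal to a fixed dipole pattern times an annual driver
  series plus noise.

All generators are deterministic for a fixed seed.  The defaults emulate the
Logrono area of the upper Ebro valley: about 405 mm of annual precipitation
concentrated in spring and autumn, July maxima near 29 degC, and a warming
trend of a few tenths of a degree per decade.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from . import bioclim

__all__ = [
    "WeatherGenConfig",
    "VintageResponseConfig",
    "LAIGridConfig",
    "TeleconnectionConfig",
    "SSTFieldConfig",
    "generate_daily_weather",
    "generate_wine_table",
    "generate_lai_grid",
    "generate_teleconnection_indices",
    "generate_sst_field",
    "may_tx_anomalies",
]

TELECONNECTION_MODES = ("nao", "ea", "eawr", "scand")


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class WeatherGenConfig:
    """Parameters of the daily weather generator.

    Temperatures follow ``seasonal sinusoid + warming trend + AR(1) anomaly``
    with a shared anomaly driving TX and TN; precipitation occurrence is a
    two-state Markov chain whose transition probabilities are scaled by
    monthly multipliers (spring/autumn maxima), and wet-day amounts are
    gamma distributed.  Sunshine, cloud and humidity are diagnosed from the
    temperature anomaly and wet/dry state.
    """

    year_start: int = 1993
    year_end: int = 2017
    latitude: float = 42.45
    tx_mean: float = 19.0       # degC, annual mean of daily maxima
    tx_amplitude: float = 9.5   # degC, half peak-to-trough seasonal swing
    tn_mean: float = 8.5
    tn_amplitude: float = 7.0
    ar1: float = 0.70           # day-to-day persistence of the anomaly
    noise_sd: float = 2.0       # degC, innovation scale of the AR(1) anomaly
    trend_per_decade: float = 0.4  # degC/decade added to TX and TN
    p_wet_wet: float = 0.45
    p_wet_dry: float = 0.25
    gamma_shape: float = 0.8
    gamma_scale: float = 4.39   # mm; shape*scale ~ 3.5 mm per wet day
    # Jan..Dec multipliers on the wet-transition probabilities; mean 1.0 so
    # the 405 mm/yr target is preserved while spring and autumn stay wettest.
    monthly_wet_multiplier: tuple = (0.9, 0.9, 1.1, 1.2, 1.2, 0.9,
                                     0.7, 0.7, 1.0, 1.2, 1.2, 1.0)
    ss_base: float = 7.5        # h/day
    ss_per_tx_sd: float = 1.2   # sunnier when anomalously warm
    ss_wet_penalty: float = 3.0
    cc_base: float = 4.0        # oktas
    cc_per_tx_sd: float = -0.8
    cc_wet_bonus: float = 2.5
    hr_base: float = 65.0       # %
    hr_per_tx_sd: float = -4.0
    hr_wet_bonus: float = 15.0

    def validate(self) -> "WeatherGenConfig":
        if self.year_end < self.year_start:
            raise ConfigurationError("year_end < year_start")
        for p in (self.p_wet_wet, self.p_wet_dry):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("Markov probabilities must lie in [0, 1]")
        if not 0.0 <= self.ar1 < 1.0:
            raise ConfigurationError("AR(1) coefficient must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise sd must be >= 0")
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ConfigurationError("gamma shape and scale must be positive")
        if len(self.monthly_wet_multiplier) != 12 or min(self.monthly_wet_multiplier) < 0:
            raise ConfigurationError("need 12 non-negative monthly multipliers")
        return self


def generate_daily_weather(config: WeatherGenConfig, seed: int) -> pd.DataFrame:
    """Generate a gap-free daily weather series for the configured years.

    Returns a DataFrame with DatetimeIndex and columns ``tx, tn, pp, ss, cc,
    hr``; TX >= TN on every day by construction, PP >= 0.
    """
    cfg = config.validate()
    rng = np.random.default_rng(seed)
    dates = pd.date_range(
        f"{cfg.year_start}-01-01", f"{cfg.year_end}-12-31", freq="D"
    )
    n = len(dates)
    doy = dates.dayofyear.to_numpy(dtype=float)
    year_len = np.where(dates.is_leap_year, 366.0, 365.0)
    # Peak around late July (lag ~0.55 of the year past Jan 1)
    phase = 2.0 * np.pi * (doy / year_len - 0.55)
    seas_tx = cfg.tx_mean + cfg.tx_amplitude * np.cos(phase)
    seas_tn = cfg.tn_mean + cfg.tn_amplitude * np.cos(phase)

    years_elapsed = (dates - dates[0]).days.to_numpy() / 365.25
    trend = cfg.trend_per_decade / 10.0 * years_elapsed

    anom = np.zeros(n)
    if cfg.noise_sd > 0:
        eps = rng.normal(0.0, cfg.noise_sd, size=n)
        anom[0] = eps[0] / np.sqrt(1.0 - cfg.ar1**2) if cfg.ar1 > 0 else eps[0]
        for i in range(1, n):
            anom[i] = cfg.ar1 * anom[i - 1] + eps[i]

    tx = seas_tx + trend + anom
    tn = seas_tn + trend + 0.8 * anom
    tn = np.minimum(tn, tx - 0.1)  # physical ordering even in odd configs

    months = dates.month.to_numpy()
    mult = np.asarray(cfg.monthly_wet_multiplier)[months - 1]
    u = rng.random(n)
    wet = np.zeros(n, dtype=bool)
    p0 = min(cfg.p_wet_dry * mult[0], 1.0)
    wet[0] = u[0] < p0
    for i in range(1, n):
        p = cfg.p_wet_wet if wet[i - 1] else cfg.p_wet_dry
        wet[i] = u[i] < min(p * mult[i], 1.0)
    pp = np.zeros(n)
    n_wet = int(wet.sum())
    if n_wet:
        pp[wet] = rng.gamma(cfg.gamma_shape, cfg.gamma_scale, size=n_wet)

    anom_sd = cfg.noise_sd / np.sqrt(1.0 - cfg.ar1**2) if cfg.noise_sd > 0 else 1.0
    z = anom / anom_sd
    ss = np.clip(cfg.ss_base + cfg.ss_per_tx_sd * z - cfg.ss_wet_penalty * wet, 0.0, 16.0)
    cc = np.clip(cfg.cc_base + cfg.cc_per_tx_sd * z + cfg.cc_wet_bonus * wet, 0.0, 8.0)
    hr = np.clip(cfg.hr_base + cfg.hr_per_tx_sd * z + cfg.hr_wet_bonus * wet, 0.0, 100.0)

    daily = pd.DataFrame(
        {"tx": tx, "tn": tn, "pp": pp, "ss": ss, "cc": cc, "hr": hr}, index=dates
    )
    return bioclim.validate_daily(daily)


def _monthly_tx_zscores(weather: pd.DataFrame, month: int) -> pd.Series:
    """Standardized anomalies of a month's mean TX across years."""
    sel = weather.loc[weather.index.month == month, "tx"]
    means = sel.groupby(sel.index.year).mean()
    sd = means.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return means * 0.0
    return (means - means.mean()) / sd


def may_tx_anomalies(weather: pd.DataFrame) -> pd.Series:
    """Standardized May mean-TX anomaly per year (used for couplings)."""
    return _monthly_tx_zscores(weather, 5)


VINTAGE_VARIABLES = ("pvad", "ph", "tta", "wb100", "veraison_doy",
                     "harvest_doy", "production", "yield")


@dataclass
class VintageResponseConfig:
    """Linear response of each vintage variable to seasonal weather.

    For each variable, ``value = baseline + b_may*zMay + b_jun*zJun +
    b_jul*zJul + b_wet*zWet + noise`` where zMay/zJun/zJul are standardized
    monthly mean-TX anomalies and zWet the standardized April-October
    precipitation anomaly.  Default signs follow the known viticultural
    response: heat raises probable alcohol and pH, lowers acidity and
    advances (lowers) veraison and harvest dates; wetness raises berry
    weight.
    """

    baselines: dict = field(default_factory=lambda: {
        "pvad": 13.0,          # % vol
        "ph": 3.60,
        "tta": 6.0,            # g/L tartaric
        "wb100": 180.0,        # g per 100 berries
        "veraison_doy": 222.0,  # ~10 August
        "harvest_doy": 275.0,   # ~2 October
        "production": 280.0,    # ML
        "yield": 6500.0,        # kg/ha
    })
    # slope per 1 sd of [May TX, Jun TX, Jul TX, wetness]
    slopes: dict = field(default_factory=lambda: {
        "pvad": (0.30, 0.25, 0.20, -0.10),
        "ph": (0.04, 0.03, 0.02, -0.01),
        "tta": (-0.35, -0.30, -0.20, 0.10),
        "wb100": (-2.0, -2.0, -1.0, 6.0),
        "veraison_doy": (-3.0, -2.5, -2.0, 1.0),
        "harvest_doy": (-3.5, -3.0, -2.5, 1.5),
        "production": (-5.0, -4.0, -3.0, 10.0),
        "yield": (-100.0, -80.0, -60.0, 250.0),
    })
    noise_sd: dict = field(default_factory=lambda: {
        "pvad": 0.25, "ph": 0.04, "tta": 0.30, "wb100": 6.0,
        "veraison_doy": 3.0, "harvest_doy": 3.5, "production": 12.0,
        "yield": 300.0,
    })
    rating_noise_sd: float = 0.7

    def validate(self) -> "VintageResponseConfig":
        for v in VINTAGE_VARIABLES:
            if v not in self.baselines or v not in self.slopes or v not in self.noise_sd:
                raise ConfigurationError(f"missing configuration for variable {v!r}")
            if self.noise_sd[v] < 0:
                raise ConfigurationError("noise sd must be >= 0")
        return self


def generate_wine_table(
    weather: pd.DataFrame,
    config: VintageResponseConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, VintageResponseConfig]:
    """Generate one vintage row per year, causally coupled to the weather.

    Returns ``(table, config)`` so the ground-truth coefficients are
    available for recovery tests.  Requires at least three full years.
    """
    cfg = (config or VintageResponseConfig()).validate()
    years = sorted(set(weather.index.year))
    if len(years) < 3:
        raise ValueError("weather must span at least 3 full years")
    rng = np.random.default_rng(seed)

    z_may = _monthly_tx_zscores(weather, 5)
    z_jun = _monthly_tx_zscores(weather, 6)
    z_jul = _monthly_tx_zscores(weather, 7)
    gs = weather.loc[(weather.index.month >= 4) & (weather.index.month <= 10), "pp"]
    pp_year = gs.groupby(gs.index.year).sum()
    sd = pp_year.std(ddof=1)
    z_wet = (pp_year - pp_year.mean()) / sd if sd > 0 else pp_year * 0.0

    predictors = np.column_stack([
        z_may.reindex(years).to_numpy(),
        z_jun.reindex(years).to_numpy(),
        z_jul.reindex(years).to_numpy(),
        z_wet.reindex(years).to_numpy(),
    ])
    table = {"year": years}
    for v in VINTAGE_VARIABLES:
        beta = np.asarray(cfg.slopes[v], dtype=float)
        noise = rng.normal(0.0, cfg.noise_sd[v], size=len(years)) if cfg.noise_sd[v] > 0 else 0.0
        table[v] = cfg.baselines[v] + predictors @ beta + noise
    df = pd.DataFrame(table).set_index("year")
    df["veraison_doy"] = df["veraison_doy"].clip(1, 366)
    df["harvest_doy"] = df["harvest_doy"].clip(1, 366)

    # Vintage rating: an ordered category driven by summer heat plus noise,
    # split at fixed latent quantiles (good : very good : excellent).
    latent = predictors[:, :3].mean(axis=1) + rng.normal(
        0.0, cfg.rating_noise_sd, size=len(years)
    )
    q1, q2 = np.quantile(latent, [0.4, 0.8])
    rating = np.where(latent <= q1, "good", np.where(latent <= q2, "very good", "excellent"))
    df["rating"] = pd.Categorical(
        rating, categories=["good", "very good", "excellent"], ordered=True
    )
    return df, cfg


@dataclass
class LAIGridConfig:
    """Monthly LAI grid: double-logistic annual cycle, summer heat coupling."""

    nlat: int = 4
    nlon: int = 5
    lat0: float = 42.3
    lon0: float = -2.8
    resolution: float = 0.0727273  # degrees, equatorial pixel size
    lai_winter: float = 0.4        # m2/m2 dormant canopy
    lai_max: float = 2.2           # m2/m2 peak canopy
    greenup_doy: float = 110.0     # ~mid/late April
    senescence_doy: float = 290.0  # ~mid October
    steepness: float = 0.08        # logistic slope, 1/day
    summer_coupling: float = -0.3  # LAI sd per sd of summer TX anomaly
    noise_sd: float = 0.08         # m2/m2 per pixel-month
    anomaly_sd: float = 0.25       # m2/m2, scale of the coupled summer anomaly
    fraction_high: float = 0.85    # vineyard fraction of "vineyard" pixels
    vineyard_fraction_seed_split: float = 0.6  # share of pixels above threshold

    def validate(self) -> "LAIGridConfig":
        if self.nlat < 2 or self.nlon < 2:
            raise ConfigurationError("grid must be at least 2x2")
        if not 0.0 <= self.fraction_high <= 1.0:
            raise ConfigurationError("fractions must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise sd must be >= 0")
        return self


def _annual_cycle(cfg: LAIGridConfig, doy: np.ndarray) -> np.ndarray:
    up = 1.0 / (1.0 + np.exp(-cfg.steepness * (doy - cfg.greenup_doy)))
    down = 1.0 / (1.0 + np.exp(-cfg.steepness * (doy - cfg.senescence_doy)))
    return cfg.lai_winter + (cfg.lai_max - cfg.lai_winter) * (up - down)


def generate_lai_grid(
    config: LAIGridConfig,
    weather: pd.DataFrame,
    seed: int = 0,
) -> tuple[xr.Dataset, pd.DataFrame]:
    """Monthly LAI field plus a per-pixel vineyard-fraction table.

    Summer (June-August) months receive a shared anomaly equal to
    ``summer_coupling * anomaly_sd * z(summer TX)`` so that hot summers thin
    the canopy when the coupling is negative.  LAI is clipped at zero.
    """
    cfg = config.validate()
    rng = np.random.default_rng(seed)
    years = sorted(set(weather.index.year))
    lats = cfg.lat0 + cfg.resolution * np.arange(cfg.nlat)
    lons = cfg.lon0 + cfg.resolution * np.arange(cfg.nlon)

    sel = weather.loc[weather.index.month.isin((6, 7, 8)), "tx"]
    tx_summer = sel.groupby(sel.index.year).mean()
    sd = tx_summer.std(ddof=1)
    z_summer = ((tx_summer - tx_summer.mean()) / sd if sd and np.isfinite(sd) and sd > 0
                else tx_summer * 0.0)

    times = pd.PeriodIndex(
        [f"{y}-{m:02d}" for y in years for m in range(1, 13)], freq="M"
    ).to_timestamp() + pd.Timedelta(days=14)
    # climatological cycle: fixed (non-leap) month midpoints for every year
    mid = np.array([
        sum(calendar.monthrange(2001, mm)[1] for mm in range(1, m)) +
        calendar.monthrange(2001, m)[1] / 2.0
        for m in range(1, 13)
    ])
    doy = np.tile(mid, len(years))
    base = _annual_cycle(cfg, doy)  # (time,)
    month_of = np.tile(np.arange(1, 13), len(years))
    year_of = np.repeat(years, 12)
    summer = np.isin(month_of, (6, 7, 8))
    coupled = np.where(
        summer,
        cfg.summer_coupling * cfg.anomaly_sd * z_summer.reindex(year_of).to_numpy(),
        0.0,
    )
    noise = (rng.normal(0.0, cfg.noise_sd, size=(len(times), cfg.nlat, cfg.nlon))
             if cfg.noise_sd > 0 else np.zeros((len(times), cfg.nlat, cfg.nlon)))
    values = base[:, None, None] + coupled[:, None, None] + noise
    values = np.clip(values, 0.0, None)

    ds = xr.Dataset(
        {"lai": (("time", "lat", "lon"), values)},
        coords={"time": times, "lat": lats, "lon": lons},
        attrs={"units": "m2/m2", "description": "synthetic monthly LAI"},
    )

    npix = cfg.nlat * cfg.nlon
    n_high = max(1, int(round(cfg.vineyard_fraction_seed_split * npix)))
    fractions = np.empty(npix)
    fractions[:n_high] = np.clip(
        cfg.fraction_high + rng.normal(0, 0.04, n_high), 0.0, 1.0
    )
    fractions[n_high:] = rng.uniform(0.05, 0.6, npix - n_high)
    order = rng.permutation(npix)
    fractions = fractions[order]
    grid_lat, grid_lon = np.meshgrid(lats, lons, indexing="ij")
    frac = pd.DataFrame({
        "pixel": np.arange(npix),
        "lat": grid_lat.ravel(),
        "lon": grid_lon.ravel(),
        "fraction": fractions,
    })
    return ds, frac


@dataclass
class TeleconnectionConfig:
    """Standardized AR(1) monthly indices for the four North Atlantic modes."""

    year_start: int = 1993
    year_end: int = 2017
    ar1: float = 0.3
    may_ea_coupling: float = 0.0  # correlation imposed between May EA and May TX

    def validate(self) -> "TeleconnectionConfig":
        if not 0.0 <= self.ar1 < 1.0:
            raise ConfigurationError("AR(1) coefficient must lie in [0, 1)")
        if not -1.0 <= self.may_ea_coupling <= 1.0:
            raise ConfigurationError("coupling must lie in [-1, 1]")
        return self


def generate_teleconnection_indices(
    config: TeleconnectionConfig,
    seed: int = 0,
    may_tx_z: pd.Series | None = None,
) -> pd.DataFrame:
    """Monthly NAO/EA/EA-WR/SCAND indices, standardized, AR(1) in time.

    When ``may_tx_z`` (standardized May TX anomalies per year) is given and
    the coupling c is nonzero, each May EA value is replaced by
    ``c * z + sqrt(1 - c^2) * noise`` so corr(May EA, May TX) ~ c.
    Indexed by (year, month).
    """
    cfg = config.validate()
    rng = np.random.default_rng(seed)
    years = list(range(cfg.year_start, cfg.year_end + 1))
    n = len(years) * 12
    out = {}
    for mode in TELECONNECTION_MODES:
        eps = rng.normal(0.0, 1.0, size=n)
        x = np.empty(n)
        scale = np.sqrt(1.0 - cfg.ar1**2)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = cfg.ar1 * x[i - 1] + scale * eps[i]
        out[mode] = x
    idx = pd.MultiIndex.from_product([years, range(1, 13)], names=["year", "month"])
    df = pd.DataFrame(out, index=idx)
    c = cfg.may_ea_coupling
    if c != 0.0 and may_tx_z is not None:
        z = may_tx_z.reindex(years).fillna(0.0).to_numpy()
        fresh = rng.normal(0.0, 1.0, size=len(years))
        df.loc[(slice(None), 5), "ea"] = c * z + np.sqrt(1.0 - c**2) * fresh
    return df


@dataclass
class SSTFieldConfig:
    """SST field = fixed dipole pattern x annual driver x coupling + noise."""

    nlat: int = 10
    nlon: int = 20
    lat0: float = -20.0
    lon0: float = 160.0
    resolution: float = 2.0
    coupling: float = 0.0
    noise_sd: float = 1.0
    pattern_scale: float = 1.0

    def validate(self) -> "SSTFieldConfig":
        if self.nlat < 2 or self.nlon < 2:
            raise ConfigurationError("grid must be at least 2x2")
        if self.noise_sd < 0:
            raise ConfigurationError("noise sd must be >= 0")
        return self


def sst_pattern(cfg: SSTFieldConfig) -> np.ndarray:
    """Fixed dipole-like spatial pattern: warm east, cold west lobes."""
    ii = np.linspace(-1.0, 1.0, cfg.nlat)[:, None]
    jj = np.linspace(-1.0, 1.0, cfg.nlon)[None, :]
    lobe = np.exp(-(ii**2) / 0.5)
    return cfg.pattern_scale * lobe * np.tanh(2.5 * jj)


def generate_sst_field(
    config: SSTFieldConfig,
    driver_series: pd.Series,
    seed: int = 0,
) -> xr.Dataset:
    """Monthly SST anomaly field driven by an annual series.

    ``SST(t, x) = coupling * pattern(x) * driver(year(t)) + noise``.  The
    driver value of a calendar year is applied to all twelve months of that
    year; the generating pattern is stored in the output for recovery tests.
    """
    cfg = config.validate()
    rng = np.random.default_rng(seed)
    years = [int(y) for y in driver_series.index]
    pattern = sst_pattern(cfg)
    times = pd.PeriodIndex(
        [f"{y}-{m:02d}" for y in years for m in range(1, 13)], freq="M"
    ).to_timestamp() + pd.Timedelta(days=14)
    driver = np.repeat(driver_series.to_numpy(dtype=float), 12)
    signal = cfg.coupling * pattern[None, :, :] * driver[:, None, None]
    noise = (rng.normal(0.0, cfg.noise_sd, size=signal.shape)
             if cfg.noise_sd > 0 else 0.0)
    lats = cfg.lat0 + cfg.resolution * np.arange(cfg.nlat)
    lons = cfg.lon0 + cfg.resolution * np.arange(cfg.nlon)
    return xr.Dataset(
        {
            "sst": (("time", "lat", "lon"), signal + noise),
            "pattern": (("lat", "lon"), pattern),
        },
        coords={"time": times, "lat": lats, "lon": lons},
        attrs={"units": "degC", "description": "synthetic monthly SST anomalies"},
    )
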