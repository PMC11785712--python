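"""End-to-end analysis chain and its configuration.

``run_report`` executes the full pipeline on synthetic (or user-supplied)
inputs: bioclimatic indices -> vintage PCA -> PC trend tests -> partial
correlations of PC scores with the indices (year as control) ->
Kruskal-Wallis of scores across vintage ratings -> tercile composites for
the station variables, the regional LAI series and the teleconnection
indices -> seasonal SST correlation map.  Every artifact is written as CSV
(gridded inputs as NetCDF) together with a JSON manifest carrying the seed,
a config hash and the package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, bioclim, composites, gridded, io, robust_stats, synthetic_data, wine_pca

__all__ = ["PipelineConfig", "run_report", "simulate_inputs", "spei_proxy"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the analysis chain, with the field-standard defaults.

    Windows: growing season April-October, Huglin April-September, Cool
    Night Index September, Dryness Index April-September, SST window
    previous December-May.  Thresholds: hot day 30 degC, frost day 0 degC,
    wet day 1 mm, vineyard fraction 0.75.  Bootstrap: 10,000 samples, 5th
    and 95th percentiles.
    """

    seed: int = 0
    weather: synthetic_data.WeatherGenConfig = field(
        default_factory=synthetic_data.WeatherGenConfig)
    vintage: synthetic_data.VintageResponseConfig = field(
        default_factory=synthetic_data.VintageResponseConfig)
    lai: synthetic_data.LAIGridConfig = field(
        default_factory=synthetic_data.LAIGridConfig)
    teleconnections: synthetic_data.TeleconnectionConfig = field(
        default_factory=synthetic_data.TeleconnectionConfig)
    sst: synthetic_data.SSTFieldConfig = field(
        default_factory=synthetic_data.SSTFieldConfig)
    n_components: int = 3
    standardize: bool = True
    vineyard_threshold: float = 0.75
    n_boot: int = 10_000
    percentiles: tuple[float, float] = (5.0, 95.0)
    alpha: float = 0.05
    sst_window: tuple[int, ...] = (12, 1, 2, 3, 4, 5)
    composite_variables: tuple[str, ...] = ("tx", "tn", "pp_total", "ss", "hr")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        nested = {
            "weather": synthetic_data.WeatherGenConfig,
            "vintage": synthetic_data.VintageResponseConfig,
            "lai": synthetic_data.LAIGridConfig,
            "teleconnections": synthetic_data.TeleconnectionConfig,
            "sst": synthetic_data.SSTFieldConfig,
        }
        for key, value in raw.items():
            if key in nested:
                kwargs[key] = nested[key](**value)
            elif key in ("percentiles", "sst_window", "composite_variables"):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def spei_proxy(monthly: pd.DataFrame) -> pd.Series:
    """Standardized water-balance proxy standing in for an external SPEI.

    Per calendar month, the z-score across years of (precipitation total
    minus a temperature-proportional demand term).  A deliberately simple
    surrogate: the real index is always consumed from an external product,
    never fitted here.
    """
    wb = monthly["pp_total"] - 2.0 * monthly["tx"]
    out = []
    for month, grp in wb.groupby(level="month"):
        sd = grp.std(ddof=1)
        out.append((grp - grp.mean()) / sd if sd > 0 else grp * 0.0)
    return pd.concat(out).sort_index().rename("spei")


def simulate_inputs(cfg: PipelineConfig) -> dict:
    """Generate the full synthetic input bundle for one seed."""
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=5)
    weather = synthetic_data.generate_daily_weather(cfg.weather, int(seeds[0]))
    vintages, truth = synthetic_data.generate_wine_table(weather, cfg.vintage, int(seeds[1]))
    lai_grid, fractions = synthetic_data.generate_lai_grid(cfg.lai, weather, int(seeds[2]))
    may_z = synthetic_data.may_tx_anomalies(weather)
    tele = synthetic_data.generate_teleconnection_indices(
        cfg.teleconnections, int(seeds[3]), may_tx_z=may_z)
    monthly = bioclim.aggregate_monthly(weather)
    spei = spei_proxy(monthly)
    return {
        "weather": weather,
        "vintages": vintages,
        "vintage_truth": truth,
        "lai_grid": lai_grid,
        "fractions": fractions,
        "teleconnections": tele,
        "monthly": monthly,
        "spei": spei,
        "sst_seed": int(seeds[4]),
    }


def _stage(name):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_report(cfg: PipelineConfig, outdir) -> dict:
    """Execute the whole chain and write all artifacts under ``outdir``.

    Returns a dict of the in-memory results.  Any stage failure raises with
    the stage name; artifacts written before the failure are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "simulate"
    try:
        t0 = _stage(stage)
        inputs = simulate_inputs(cfg)
        io.write_station_csv(inputs["weather"], outdir / "station.csv")
        io.write_vintage_csv(inputs["vintages"], outdir / "vintages.csv")
        io.write_index_table(inputs["teleconnections"], outdir / "teleconnections.txt")
        io.write_netcdf_grid(inputs["lai_grid"], outdir / "lai.nc")
        io.write_fraction_table(inputs["fractions"], outdir / "fractions.csv")
        io.write_spei_csv(inputs["spei"], outdir / "spei.csv")

        stage = "indices"
        _stage(stage)
        lat = cfg.weather.latitude
        indices = bioclim.bioclim_table(inputs["weather"], lat, inputs["spei"])
        indices.to_csv(outdir / "bioclim.csv", float_format="%.6g")
        results["bioclim"] = indices

        stage = "pca"
        _stage(stage)
        decomp = wine_pca.run_pca(
            inputs["vintages"], n_components=cfg.n_components,
            scaling="center+standardize" if cfg.standardize else "center")
        decomp.loadings.to_csv(outdir / "pca_loadings.csv", float_format="%.6g")
        decomp.scores.to_csv(outdir / "pca_scores.csv", float_format="%.6g")
        decomp.explained_fraction.rename("explained_fraction").to_csv(
            outdir / "pca_variance.csv", float_format="%.6g")
        results["pca"] = decomp

        stage = "trends"
        _stage(stage)
        trend_rows = []
        for comp in decomp.scores.columns:
            tr = wine_pca.score_trend_report(decomp, comp)
            trend_rows.append({
                "component": comp, "S": tr.S, "z": tr.z, "p": tr.p_two_sided,
                "sen_slope": tr.sen_slope, "ci_lo": tr.slope_ci[0],
                "ci_hi": tr.slope_ci[1],
            })
        trends = pd.DataFrame(trend_rows).set_index("component")
        trends.to_csv(outdir / "pc_trends.csv", float_format="%.6g")
        results["trends"] = trends

        stage = "partial_correlations"
        _stage(stage)
        years = decomp.scores.index.to_numpy(dtype=float)
        rows = []
        common = indices.index.intersection(decomp.scores.index)
        for comp in decomp.scores.columns:
            for var in indices.columns:
                x = decomp.scores.loc[common, comp].to_numpy()
                y = indices.loc[common, var].to_numpy(dtype=float)
                if not np.all(np.isfinite(y)):
                    continue
                try:
                    r, p = robust_stats.partial_correlation(
                        x, y, np.asarray(common, dtype=float))
                except robust_stats.DegenerateControlError:
                    continue
                rows.append({"component": comp, "variable": var, "r_partial": r, "p": p})
        pcorr = pd.DataFrame(rows)
        pcorr.to_csv(outdir / "partial_correlations.csv", index=False, float_format="%.6g")
        results["partial_correlations"] = pcorr

        stage = "rating_tests"
        _stage(stage)
        rating_rows = []
        ratings = inputs["vintages"]["rating"]
        for comp in decomp.scores.columns:
            groups = [decomp.scores.loc[ratings.index[ratings == cat], comp].to_numpy()
                      for cat in ratings.cat.categories]
            groups = [g for g in groups if g.size > 0]
            if len(groups) < 2:
                continue
            h, p = robust_stats.kruskal_wallis(groups)
            rating_rows.append({"component": comp, "H": h, "p": p})
        kw = pd.DataFrame(rating_rows)
        kw.to_csv(outdir / "rating_kruskal.csv", index=False, float_format="%.6g")
        results["rating_tests"] = kw

        stage = "composites"
        _stage(stage)
        pc1 = decomp.scores["PC1"]
        comp_tables = []
        boot_seed = int(np.random.default_rng(cfg.seed + 1).integers(0, 2**31 - 1))
        monthly = inputs["monthly"]
        for var in cfg.composite_variables:
            if var not in monthly.columns:
                continue
            res = composites.composite_report(
                monthly[var], pc1, n_boot=cfg.n_boot,
                percentiles=cfg.percentiles, seed=boot_seed)
            tidy = res.to_frame()
            tidy.insert(0, "variable", var)
            comp_tables.append(tidy)

        mask = gridded.select_vineyard_pixels(inputs["fractions"], cfg.vineyard_threshold)
        lai_series = gridded.regional_lai_series(inputs["lai_grid"], mask)
        if not lai_series.empty:
            gridded.annual_cycle_summary(lai_series).to_csv(
                outdir / "lai_annual_cycle.csv", float_format="%.6g")
            res = composites.composite_report(
                lai_series, pc1, n_boot=cfg.n_boot,
                percentiles=cfg.percentiles, seed=boot_seed)
            tidy = res.to_frame()
            tidy.insert(0, "variable", "lai")
            comp_tables.append(tidy)

        for mode in synthetic_data.TELECONNECTION_MODES:
            res = composites.composite_report(
                inputs["teleconnections"][mode], pc1, n_boot=cfg.n_boot,
                percentiles=cfg.percentiles, seed=boot_seed)
            tidy = res.to_frame()
            tidy.insert(0, "variable", mode)
            comp_tables.append(tidy)
        comp_df = pd.concat(comp_tables, ignore_index=True)
        comp_df.to_csv(outdir / "composites.csv", index=False, float_format="%.6g")
        results["composites"] = comp_df

        stage = "sst_map"
        _stage(stage)
        pc1_detr = pc1 - np.polyval(np.polyfit(years, pc1.to_numpy(), 1), years)
        sst_grid = synthetic_data.generate_sst_field(
            cfg.sst, pc1_detr, seed=inputs["sst_seed"])
        io.write_netcdf_grid(sst_grid, outdir / "sst.nc")
        sst_table = gridded.seasonal_sst_mean(sst_grid, cfg.sst_window)
        r, sig, thr = gridded.correlation_map(pc1, sst_table, alpha=cfg.alpha)
        sst_map = pd.DataFrame({"r": r, "significant": sig, "critical_r": thr})
        sst_map.index.name = "pixel"
        sst_map.to_csv(outdir / "sst_correlation_map.csv", float_format="%.6g")
        results["sst_map"] = sst_map

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "config": cfg.to_dict(),
            "artifacts": sorted(
                {p.name for p in outdir.iterdir() if p.is_file()} | {"manifest.json"}),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        results["manifest"] = manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results
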