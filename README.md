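# vinoclim

Statistical diagnostics linking regional climate variability to wine-vintage
composition and phenology, built for viticulture climatology of
Mediterranean-continental regions such as the upper Ebro valley (Rioja).

Vintage records — must chemistry (probable alcohol PVAD, pH, total tartaric
acidity TTA), berry weight, veraison and harvest dates, production and yield
— respond strongly to late-spring and summer weather. `vinoclim` implements
the full analysis chain used to quantify that response:

* **Bioclimatic indices** from daily station data: Growing Degree Days
  `GDD = Σ max(0, (TX+TN)/2 − 10 °C)` over April–October; the Huglin
  heliothermal index `HI = Σ K·max(0, ((T − 10) + (TX − 10))/2)` over
  April–September with the latitude-dependent day-length coefficient K; the
  Cool Night Index (mean September TN); the Dryness Index (end-of-September
  soil-water reserve from a monthly vine water balance starting at 200 mm);
  hot-day (TX > 30 °C), frost-day (TN < 0 °C) and wet-day (PP > 1 mm)
  counts; and windowed extraction of externally supplied SPEI drought
  values.
* **Vintage PCA**: mean-centered (optionally standardized) principal
  components of the annual vintage table, with a deterministic sign
  convention so that high PC1 means hot-year maturity (alcohol and pH load
  positively, acidity and phenological dates negatively).
* **Nonparametric statistics**, written out in full: Mann-Kendall trend test
  with tie-corrected variance and continuity correction, Theil-Sen slopes
  with rank-based confidence intervals, first-order partial correlation
  (year as the control variable), Kruskal-Wallis, Conover-Iman post-hoc
  comparisons, and the critical Pearson-r threshold
  `r* = t*/√(n − 2 + t*²)` (0.40 at n = 25, α = 0.05).
* **Tercile composites**: per-calendar-month linear detrending, tercile
  classification of an annual index (8-year extreme sets for 25 years), and
  composite monthly anomalies of extreme-tercile years tested against 5th/95th
  percentile envelopes from 10,000 bootstrap samples of same-size year sets.
* **Gridded diagnostics**: vineyard pixel selection by a ≥ 75% land-cover
  fraction rule, regional LAI phenology series, previous-December-to-May SST
  windows, and correlation maps with per-pixel analytic significance
  masking.
* **A synthetic-data generator** producing weather, vintages, LAI grids,
  teleconnection indices (NAO, EA, EA/WR, SCAND) and SST fields with known,
  configurable couplings, so every stage has a parameter-recovery test
  surface. Real vintage archives of this kind are typically confidential;
  the generator's defaults emulate the study conditions (25 years, ~405 mm
  annual precipitation, a warming trend of a few tenths of a °C per decade).

## Worked example

```python
from vinoclim import synthetic_data as sd, bioclim, wine_pca, composites

weather = sd.generate_daily_weather(sd.WeatherGenConfig(), seed=42)
table, truth = sd.generate_wine_table(weather, seed=43)

indices = bioclim.bioclim_table(weather, latitude=42.45)
print(indices[["gdd", "hi", "ci", "di", "hd", "wd"]].round(1).head(3))

decomp = wine_pca.run_pca(table)
print("explained variance:", (100 * decomp.explained_fraction).round(1).to_dict())
trend = wine_pca.score_trend_report(decomp)
print(f"PC1 trend: Sen slope {trend.sen_slope:.3f}/yr, MK p = {trend.p_two_sided:.4f}")

monthly = bioclim.aggregate_monthly(weather)
report = composites.composite_report(monthly["tx"], decomp.scores["PC1"],
                                     n_boot=10_000, seed=0)
print(report.to_frame().query("significant").round(2).to_string(index=False))
```

Output:

```
         gdd      hi    ci    di  hd  wd
year
1993  1673.4  2141.9  12.4  72.7  20  47
1994  1663.9  2141.0  11.5  81.6  13  54
1995  1718.6  2204.9  13.1  53.0  28  51
explained variance: {'PC1': 62.2, 'PC2': 15.3, 'PC3': 7.0}
PC1 trend: Sen slope 0.184/yr, MK p = 0.0014
 month category  composite    lo   hi  significant
     5     high       0.97 -0.61 0.64         True
     2      low       0.99 -0.68 0.77         True
     6      low      -0.83 -0.53 0.52         True
    10      low       0.56 -0.48 0.47         True
```

Reading it: this synthetic 25-year run accumulates ~1700 degree-days per
growing season with 13–28 hot days a year. PC1 of the vintage table carries
62% of the variance and trends upward (Sen slope 0.18 score units/yr,
Mann-Kendall p ≈ 0.001) because the generator imposes a warming trend that
drives alcohol and pH up and acidity and harvest dates down. The composite
table lists the month/category cells whose mean maximum-temperature anomaly
escapes the bootstrap envelope — here May of high-PC1 years was ~1 °C warmer
than normal, the expected fingerprint of the injected May–July heat
coupling.

## Command line

```bash
vinoclim simulate --seed 1 --out inputs/        # synthetic input bundle
vinoclim indices --station inputs/station.csv --out bioclim.csv
vinoclim pca --vintages inputs/vintages.csv --out pca/
vinoclim report --seed 1 --out results/         # the whole chain
```

`vinoclim report` writes every artifact (bioclimatic table, PCA loadings and
scores, trend tests, partial correlations, rating tests, composites, SST
correlation map) plus a manifest with the seed and a config hash;
re-running with the same seed reproduces the outputs byte for byte.

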