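# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the known limitations of `vinoclim`.

## The analysis chain

The pipeline estimates how interannual climate variability imprints on wine
vintages. Its stages, in order:

1. **Monthly aggregation and bioclimatic indices.** Daily station records
   (TX, TN, PP, SS, CC, HR) are averaged (PP summed) per calendar month, and
   annual indices are computed over fixed windows: GDD (base 10 °C,
   April–October), Huglin HI (April–September), Cool Night Index
   (September), Dryness Index (April–September), and hot/frost/wet day
   counts with strict thresholds (TX > 30 °C, TN < 0 °C, PP > 1 mm). The
   daily mean temperature is `(TX + TN)/2` throughout — the convention of
   the index literature, since daily means are rarely archived alongside
   extremes.
2. **Vintage PCA.** The annual vintage table is mean-centered and, by
   default, also standardized before eigendecomposition, because the
   variables mix units of very different scales (% vol, g/L, grams,
   day-of-year, hL). Covariance-matrix PCA (`scaling="center"`) is exposed
   for users whose variables share units.
3. **Trends and associations.** Mann-Kendall/Theil-Sen for monotone trends;
   partial correlation with the observation year as the control variable,
   which removes shared linear trends before association between PC scores
   and bioclimatic indices is judged; Kruskal-Wallis plus Conover-Iman
   across ordered vintage-rating categories.
4. **Tercile composites.** For each monthly variable, a linear trend in
   year is removed per calendar month; the annual index is detrended and
   split into terciles (extreme sets of `floor(n/3)` years, 8 of 25); the
   high- and low-set mean monthly residuals are compared against 5th/95th
   percentile envelopes from 10,000 resampled year sets of the same size.
5. **Gridded diagnostics.** Vineyard pixels are those with land-cover
   fraction ≥ 0.75 (boundary inclusive); the regional LAI series is their
   unweighted mean (pixels in one latitude band are near equal-area; area
   weighting is available). SST fields are averaged over the
   previous-December-to-May window and correlated, after detrending, with
   the index series; pixels are masked at the analytic critical r for their
   own (pairwise-complete) sample size.

## Nonparametric statistics

* **Mann-Kendall**: `S = Σ_{i<j} sign(x_j − x_i)`, variance
  `[n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18` over tie groups, ±1 continuity
  correction, two-sided normal p-value. The normal approximation is
  standard at the series lengths this pipeline targets (n ≈ 25); the exact
  permutation distribution is not implemented, nor are prewhitened or
  seasonal variants (the score series are approximately serially
  uncorrelated by construction after PCA).
* **Theil-Sen**: median of all pairwise slopes; duplicate time values are
  excluded pairs. The confidence interval is Sen's rank-based construction
  with offset `z√var(S)` on the ordered slopes, clamped so the interval
  always contains the point estimate.
* **Partial correlation**: the first-order formula
  `(r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²))` with a t test on n − 3 df; the
  test suite verifies its exact equivalence to correlating OLS residuals.
  Controls collinear with an input raise a dedicated error.
* **Conover-Iman**: rank-mean t statistics with Conover's pooled rank
  variance and the `(N−1−H)/(N−k)` factor, N − k df. Holm adjustment is the
  default (raw p-values are always reported alongside); no multiplicity
  treatment is applied to the partial-correlation table, which is reported
  raw.
* **Critical r**: `r* = t*/√(n−2+t*²)`; at n = 25, α = 0.05 this is 0.396,
  i.e. the familiar ±0.40 map-masking threshold.

## The synthetic-data model

The generator supplies every input with known causal couplings:

* **Weather**: TX and TN are sinusoidal seasonal cycles (annual means
  19.0/8.5 °C, amplitudes 9.5/7.0 °C, peak in late July) plus a shared
  AR(1) anomaly (lag-1 coefficient 0.7, innovation sd 2 °C) and a linear
  warming trend (0.4 °C/decade by default). Precipitation occurrence is a
  two-state Markov chain (p(wet|wet) = 0.45, p(wet|dry) = 0.25) with
  monthly multipliers that keep spring and autumn wettest while averaging
  1.0; wet-day amounts are Gamma(0.8, 4.39 mm). These values were chosen
  once to emulate a Mediterranean-continental station with ~405 mm/yr;
  a 30-year run reproduces that total within a few percent. Sunshine, cloud
  and humidity are diagnosed linearly from the temperature anomaly and the
  wet/dry state, clipped to physical ranges.
* **Vintages**: each variable is `baseline + β·[z(May TX), z(Jun TX),
  z(Jul TX), z(wetness)] + noise`, with documented default signs (heat
  raises PVAD and pH, lowers TTA and advances the phenological dates;
  wetness raises berry weight). The generator returns the coefficients it
  used, so recovery tests never guess the truth.
* **LAI**: a double-logistic annual cycle (green-up ~day 110, senescence
  ~day 290, winter floor 0.4, summer plateau 2.2 m²/m²) evaluated at fixed
  non-leap month midpoints — the cycle is climatological, so leap-day
  shifts are deliberately not modelled — plus a summer (JJA) anomaly
  proportional to the standardized summer TX anomaly (default coefficient
  −0.3) and pixel noise, clipped at zero.
* **Teleconnections**: four independent standardized AR(1) monthly series;
  an optional imposed May EA–May TX coupling c replaces May EA values by
  `c·z + √(1−c²)·ε`.
* **SST**: `coupling · pattern(x) · driver(year) + noise`, with a fixed
  zonal-dipole pattern stored in the output dataset for recovery tests.

What the generator does **not** emulate: spatial coherence of weather
across stations, serial correlation of vintage noise, non-Gaussian vintage
responses, irrigation/management effects, satellite-retrieval artifacts in
LAI, and ENSO dynamics beyond a static spatial pattern. Passing tests
demonstrate that the pipeline recovers known couplings under this idealized
model — not that the couplings exist, or are linear, in any real region.

## Numerical and design choices

* **Detrending** means removing a per-calendar-month least-squares line in
  year (residual = original − fitted trend). This makes composites exactly
  invariant to any linear-in-year trend added to the input and keeps months
  independent; subtracting a smoothed series is a plausible alternative
  reading of the procedure but is not implemented.
* **Bootstrap envelopes** default to drawing year sets *with* replacement
  (the standard bootstrap); a `replace=False` subsampling mode draws
  without replacement. One set of year draws per replicate is reused across
  all calendar months, preserving cross-month dependence in the envelope.
  Calibration note: under a null coupling the high-tercile set is a random
  8-of-25 subset *without* replacement, whose composite variance is smaller
  than that of a with-replacement draw by roughly the finite-population
  factor (1 − (m−1)/(n−1))·n/(n−1) ≈ 0.74; with-replacement envelopes are
  therefore mildly conservative (~6% escape rate instead of the nominal
  10%). The subsampling mode is exactly calibrated for that null and is
  what the calibration tests use; the default remains the classical
  bootstrap.
* **Tercile ties** straddling a boundary are broken by year order (the
  earlier year enters the extreme set), deterministically and logged.
* **PCA signs**: the largest-magnitude loading of each component is made
  positive; PC1 is additionally flipped if needed so PVAD loads positively.
  Scores are reported unscaled (singular-value magnitude), zero-mean.
* **Huglin K**: stepwise table 1.02/1.03/1.04/1.05/1.06 at
  40/42/44/46/48–50° with linear interpolation, symmetric in hemisphere,
  clamped outside the table; ~42.45° N gives K ≈ 1.03.
* **Dryness Index**: monthly balance `W ← min(200, W + P − k·PET −
  (PET/N)(1−k)·JPm)` with k = 0.1 (April), 0.3 (May), 0.5 (June–September)
  and JPm = min(N/5, wet-day count); W may go negative. PET defaults to
  Thornthwaite's monthly formula (needs only monthly mean temperature and
  latitude) and is pluggable — Hargreaves or measured PET can be
  substituted as a month→mm mapping.
* **SPEI** is consumed from an external product and only windowed:
  July–September ("SPEI3"), March–September ("SPEI6" — seven months despite
  the conventional label; the window is explicit in code), and previous
  October–September ("SPEI12"). The pipeline's synthetic runs use a simple
  standardized water-balance proxy clearly labelled as such.
* **Pixel geometry** uses a spherical Earth (R = 6371 km); the 0.75
  coverage rule is applied to the fraction itself, not to a derived pixel
  area.
* **NetCDF** I/O uses the classic (NetCDF3) format through xarray's scipy
  backend, which keeps the gridded interchange dependency-light.

## Problem sizes

The test suite and the acceptance script run Monte-Carlo checks at sizes
chosen to make binomial error small relative to the asserted margins:
100–200 replicates for detection/recovery rates, 1,000 null draws for
envelope calibration, 400–1,000 bootstrap samples per envelope inside
replicated loops (the full 10,000 is used for single analyses, as in the
worked example). Analyses of a single 25-year dataset complete in well
under a second; the full replicated suite runs in about a minute on one
core.

## Known limitations

* The Mann-Kendall p-value is asymptotic; for n < 10 the exact distribution
  would be preferable.
* Composite significance is per-month; no field-significance or
  false-discovery control is applied across months (matching standard
  practice for this diagnostic, but multiple-testing caveats apply when
  scanning many variables).
* The partial-correlation control is a single linear year term; nonlinear
  common trends are not removed.
* The LAI regional mean ignores the small within-band area differences of
  pixels (an area-weighted variant is available).
* The vintage rating is generated as an ordered category from a latent
  heat/noise variable; real rating processes include market and stylistic
  factors with no climatic analogue here.
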