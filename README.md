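# vegwater

Country-scale analysis of vegetation growth versus water scarcity from
satellite-style time series — a tested, reusable pipeline from raw 16-day
NDVI composites with quality flags to annual vegetation-growth metrics,
trend and correlation maps, irrigation-intensity scores and land-cover
change accounts. Everything runs end to end on a built-in synthetic scene
generator with known ground truth, so no satellite downloads are needed to
develop, test or audit the methods.

It is aimed at remote-sensing and eco-hydrology practitioners who study
semi-arid regions where agricultural water use, groundwater decline and
vegetation dynamics interact.

## The statistics at the core

- **NDVI_MEAN\***: annual vegetation growth of a pixel, the mean of the X
  highest of the 23 sixteen-day NDVI composites of a water year
  (October–September). X is fixed per pixel from the maximum snow
  duration, X = max(23 − MaxSnowComposites − 1, 1), so long snow periods
  cannot inject interpolation artefacts into the annual mean.
- **Upper-envelope reconstruction**: QA masking (quality code > 2 or snow
  flag), linear gap interpolation, then iterative Savitzky–Golay smoothing
  toward the upper NDVI envelope (noise such as clouds only lowers NDVI).
- **Trends**: Theil–Sen slope (median of pairwise slopes) with the
  Mann–Kendall test under the Hamed–Rao variance correction, which inflates
  Var(S) by significant rank autocorrelations to control the type-I error
  on serially dependent annual series.
- **Irrigation intensity**: monthly irrigation probability
  IrrProb = VegProb·CropProb·WaterProb from monthly-maximum NDVI, cropland
  fraction, and the two-month aridity index ai₂ = Σtp/|Σpev|; annual
  intensity IrrIntAnn4Q averages the top quartile (3 of 12) of the monthly
  values, reported ×100.
- **Land-cover change**: 22→7 class merge, per-class annual net rates
  (gain − loss), cumulative change, ranked transition matrices, and
  correlation of net rates with water-year (12-month) and prolonged
  (15-month) meteorological aggregates.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from vegwater import GeneratorConfig, PipelineConfig, run_all

cfg = PipelineConfig(generator=GeneratorConfig(seed=1))  # 64x64, 2001-2019
res = run_all(cfg)
print(res.summary["agri_trends"])
print(res.summary["twsa"]["excluded_years"])
print(round(res.summary["warming_trend_k_per_yr"], 4))
```

prints

```
{'n_significant': 547, 'significant_positive_km2': 25.6875,
 'significant_negative_km2': 8.5, 'share_positive_pct': 75.14}
[2017, 2018]
0.0446
```

meaning: of the 547 cropland pixels with a significant (p < 0.05)
NDVI_MEAN\* trend, 75% are positive (intensifying cultivation) covering
25.7 km², against 8.5 km² of declining cropland; the two water years
overlapping the 11-month storage-mission gap are excluded from all TWSA
statistics; and the Theil–Sen slope of country-mean air temperature
recovers the scene's injected warming of 0.045 K/yr.

The same pipeline is available from the shell
(`vegwater run-all --seed 1 --out results/run`), and the numbered scripts
under `analysis/` walk through the stages one at a time — scene generation,
NDVI reconstruction fidelity, annual growth, classification, hydromet,
trends, correlations, irrigation and land cover — each printing what it
found and writing its tables under `results/`.

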