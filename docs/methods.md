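# Methods

`vegwater` re-implements a country-scale analysis chain linking satellite
vegetation time series to hydrometeorological water availability, land-cover
change and irrigation, exercised end to end on a synthetic scene with known
ground truth. This note documents the models, the defaults and why, the
numerical choices, and what the synthetic tests do and do not show.

## Temporal frame

All annual statistics use the hydrological *water year* October–September,
labelled by the calendar year of its September end. Vegetation is observed
as 23 sixteen-day NDVI composites per water year; meteorology and water
storage are monthly. Composites are assigned to calendar months by their
start date (every month receives at least one composite; May receives
three).

## NDVI reconstruction

Per pixel the continuous multi-year composite series is reconstructed in
three steps:

1. **QA masking.** A composite is masked when its quality code exceeds 2
   (degraded retrieval) or the possible-snow/ice flag is set.
2. **Gap interpolation.** Masked positions are filled linearly between the
   closest unmasked neighbours in time; leading/trailing gaps take the
   nearest valid value (nearest-value extension avoids extrapolation
   overshoot). Interpolation deliberately crosses water-year boundaries —
   the series is physically continuous, and masking near year edges would
   otherwise be unfillable.
3. **Upper-envelope smoothing.** An iterative Savitzky–Golay scheme under
   the model that residual noise (clouds, aerosol) only lowers NDVI: fit
   SG(window, polyorder); replace values below the fit by the fitted value;
   re-fit; track a fitting-effect index (absolute deviation of the fit from
   the original series, weight 1 at points on/above the first fit and
   1 − d/dmax below it); stop when the index stops decreasing or after
   `max_iterations`, returning the best-index fit. Defaults: window 7
   composites (≈ 112 days), polyorder 2, 10 iterations — values in the
   range customary for this family of local smoothers; all configurable.

Known limitation: the smoother is not a projection. Re-smoothing an already
smoothed series still changes it by ~7×10⁻³ RMS (inherent SG peak
shrinkage on seasonal pulses); a second pass is a contraction but not an
identity. Narrow seasonal peaks are flattened by up to ~0.06; recovery of
isolated negative dips on broad seasonal curves is accurate to ≤ 0.04.

## Annual vegetation growth

The annual statistic NDVI_MEAN\* is the mean of the X largest of the 23
composite values of a water year; NDVI_MAX is the annual maximum. X is
fixed per pixel from the maximum snow duration over all years,
`X = max(23 − MaxSnowComposites − 1, 1)`, with MaxSnowComposites counted in
16-day composites. The extra −1 is a safety margin against partially snowy
composites. A configuration switch accepts calendar snow days and converts
with ceil(days/16). Fixing X across years keeps the statistic comparable
between snow-rich and snow-poor years and makes it provably insensitive to
values at the excluded snow composites.

## Land-use classification

- *Vegetated*: NDVI_MAX > 0.25 in at least two years (strict comparisons
  throughout; equality falls outside the class).
- *Agricultural*: vegetated and aggregated cropland fraction
  (CropFrac, block average of the fine fraction raster) > 20%.
- *Natural*: vegetated and CropFrac < 40%.
- The band 20–40% belongs to both classes by design, absorbing mixed pixels
  and fraction-product uncertainty.
- *Newly cultivated* (excluded from trend-attribution analyses): the median
  NDVI_MAX of the late window 2009–2019 exceeds that of the first three
  years by more than 0.1 while the early median is below 0.3. The
  difference is oriented late-minus-early so that the rule flags areas that
  *became* cropland; an `as_printed` switch restores the opposite
  (published) sign for audit. The late window follows the explicit year
  range 2009–2019 (eleven labels).

## Trend detection

Magnitude: Theil–Sen slope, the median of all pairwise slopes (exact pair
enumeration; n is one value per water year). Significance: Mann–Kendall S
with tie-corrected variance, inflated by the Hamed–Rao autocorrelation
correction: the correction ratio sums `(n−i)(n−i−1)(n−i−2)·ρ_s(i)` over
lags 1..n−3 whose rank autocorrelation is significant in a two-sided
normal test at 0.05 (`|ρ| > z₀.₉₇₅/√n`). The ratio is floored at 10⁻²
(degenerate negative sums are possible at small n), a ±1 continuity
correction is applied to S (so |S| = 1 maps to z = 0), and p-values are
two-sided normal. Default α = 0.05.

## Hydrometeorology

Water-year aggregates are means by default (sums available; the aridity
index is invariant to the common factor 12). Potential evaporation follows
the reanalysis sign convention (negative); all aridity ratios use its
absolute value so that ai = tp/|pev| is a positive dryness ratio. The
two-month index ai₂(m) uses the current plus previous month; the first
series month is undefined. Z-scores standardise against a reference period
(≥ 3 years) with the sample standard deviation (n−1), appropriate for the
short common-availability reference.

Basin TWSA series: isolated missing months (runs of length 1) are filled by
a cubic spline over the month index; the long inter-mission block (11
months by default, July of year N−2 to May of year N−1) is left unfilled
and both overlapping water years are excluded from annual means.

## Irrigation intensity

Monthly irrigation probability is the product of three factors computed on
monthly-maximum NDVI, cropland fraction and ai₂:

- VegProb = 1 − exp(−(NDVI − 0.2)/0.08), 0 below NDVI 0.2;
- CropProb = (CropFrac − 20)/20 on (20, 40), 1 above 40%, undefined below
  20% (the published "+1" offset would exceed 1 and is kept only behind an
  `as_printed` audit switch);
- WaterProb = 1 below ai₂ = 0.2, 0.2 above 0.65, linear between (range
  exactly [0.2, 1]).

Annual intensity IrrIntAnn4Q averages the upper quartile — the three
largest defined values — of the twelve monthly probabilities; years with
fewer than three defined months are undefined. The initial intensity of a
pixel is the mean over the water years 2001–2003 (the two-year 2001/2003
variant is configurable) and is reported ×100.

## Land cover

Annual categorical maps in 22 raw codes are merged to 7 compound classes
(crops, trees, shrubs/sparse vegetation/grassland, inundated, urban, bare,
water) through an editable mapping table; the shipped default is a
reconstruction consistent with the class names, not an authoritative
product table. Change accounting reports per-class annual gains, losses
and net rates (km², default 0.0625 km²/pixel at 250 m — the synthetic
scene uses NDVI-grid pixels), cumulative percent change against the first
year, min–max-normalised area curves, first-to-last transition matrices
with ranked off-diagonal transitions, and Pearson correlation of net rates
with meteorology aggregated over the 12-month water year and a prolonged
15-month window. A minimum-duration debouncing filter (reverting one-year
flips) exists but is off by default: temporal consistency is treated as a
property of the input product.

## Resampling

All grids are axis-aligned with integer block ratios and pixel-centre
registration, so resampling is exact: nearest neighbour replicates the
containing coarse cell (met → pixel grid), average takes the block mean
(fine crop fraction → pixel grid), bilinear uses 4-neighbour weighting with
edge clamping (DEM → pixel grid).

## The synthetic scene

The generator emulates the statistical structure of the real archives with
known truth; defaults define the reference scene used throughout:

- 64×64 pixels, 19 water years (2001–2019), 23 composites/year.
- Seven phenology classes built from double-logistic pulses: bare,
  sparse/dense natural vegetation, single- and double-cycle cropland,
  abandoned cropland (persistent amplitude drop after the mid-period break
  year) and intensifying cropland. Class assignment is stratified by the
  west–east aridity gradient (long-term cell ai ≈ 0.64 down to 0.02).
- Injected inter-annual drifts: +0.005/yr (dense natural, intensifying
  crops), −0.005/yr (sparse natural), 0 elsewhere — the trend magnitudes
  the trend-recovery checks target.
- Rain-sensitive classes scale their pulse amplitude with a shared annual
  wet/dry anomaly (relative sd 0.25); irrigated classes are decoupled.
  Irrigated cropland (double-cycle, intensifying, abandoned, and
  single-cycle cropland in cells with ai < 0.25) grows in the dry summer;
  rainfed cropland peaks in the wet spring — the contrast the irrigation
  scoring keys on.
- Contamination: Gaussian composite noise (sd 0.02), per-year level noise
  (sd 0.01, the NDVI_MEAN*-scale noise of the trend-recovery conditions),
  negative-only outliers at rate 0.10 (value × U(0.1, 0.6), 90% flagged
  degraded, 10% silent to stress the envelope smoother beyond QA masking),
  and winter snow composites (NDVI −0.05, flagged) at high elevations.
- Meteorology on an 8×8-pixel-per-cell coarse grid (mimicking the 0.1° vs
  250 m scale gap): winter-peaked precipitation (~75% November–April),
  summer-peaked negative potential evaporation, warming 0.045 K/yr.
- Ancillary truth: fine (2×) crop-fraction raster separating cropland
  (>20%) from the rest (<20%); 3% of bare pixels scripted to convert to
  cropland in year 5 (the newly-cultivated recovery target); land-cover
  maps with anomaly-coupled sparse↔bare flips recorded exactly; four
  quadrant basins with declining TWSA (−10 mm/yr) and the 11-month gap;
  a north-high DEM driving snow duration.

What passing tests show — and do not. The scene reproduces the *structure*
of the real inputs (seasonality, contamination model, scale gaps, gaps in
the storage record), so green tests demonstrate that each operation
implements its contract and that the chain recovers known signals under
realistic noise. They do not demonstrate performance on real archives:
real QA flags are bit fields, real phenology is more diverse than seven
classes, geolocation/projection effects are absent (affine grids only),
and land-cover error is scripted rather than classifier-driven. Headline
country-scale magnitudes of the motivating study depend on the full
archives and are out of desk-scale reach by design.

## Reproducibility

Every random draw flows from one integer seed through named
`numpy.random.SeedSequence` child streams; regenerating a scene is
bit-identical, and two full pipeline runs with the same seed produce
byte-identical summary JSON. Problem sizes used by the shipped checks
(64×64×19 reference scene; 2000 replicates for the type-I Monte Carlo;
exhaustive enumeration up to length-8 series) were chosen to make the
whole suite run in minutes on a single core.
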