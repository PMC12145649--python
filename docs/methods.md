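# Methods

This note documents the models, numerical choices and known limitations of
`heatcrossover`, in the spirit of a statistical package's model
documentation.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study frame and synthetic generator

The package targets warm-season (May–September) analyses over multiple
years at the resolution of small postal regions.  Because real analyses of
this design rely on restricted health registries, the generator in
`heatcrossover.synthetic` emulates the complete study frame; its defaults
*are* the study conditions the rest of the package is tested under:

| parameter | default | meaning |
|---|---|---|
| `n_years` | 10 | seasons simulated (2005–2014 calendar) |
| `months` | {5..9} | May–September analysed frame |
| `grid_shape` | 12×12 | grid cells (1 km each, `cell_size_km`) |
| `n_regions` | 9 | region polygons tiling the grid |
| `seasonal_mean_amp` | 8 °C | half-sine seasonal amplitude over a 22 °C base |
| `spatial_sd` | 3 °C | stationary SD of the spatially correlated anomaly |
| `spatial_corr_range_km` | 6 km | e-folding range of the exponential covariance |
| `daily_ar1_rho` | 0.8 | AR(1) persistence of the anomaly |
| `noise_sd` | 0.4 °C | white measurement noise |
| `burst_rate` | 2.2/season | Poisson rate of synoptic heat bursts |
| `burst_amp_c` | 7 °C (SD 2) | grid-wide burst amplitude |
| `true_log_rr` | ln 1.29 | embedded exposure effect |
| `baseline_rate` | 2/region-day | event rate scale |
| `overdispersion` | 1.5 | variance/mean ratio φ of daily counts |

**Weather.** Daily maximum temperature is a seasonal half-sine plus a
spatially correlated AR(1) anomaly (exponential covariance over cell
centres, one Cholesky factor reused across days; seasons re-initialised
independently) plus white noise, plus a *heat-burst* component: rare
two-day, grid-wide temperature surges.  The bursts are essential, not
decorative.  Days above the pooled 99th percentile are 1% of days by
construction (≈15 per region-decade), and for a first-order autoregression
with exceedance persistence π the expected number of multi-day exceedance
runs is ≈ 15·(1−π)·π ≤ 3.75 per decade — too few for most seasons to
contain a two-day run, no matter how π is chosen.  Only a process whose
extreme days arrive in pairs (which is what synoptic heat domes produce)
makes two-day events common enough that every pipeline stage sees
non-degenerate exposure in at least half of the region-seasons.  On burst
days the AR anomaly is damped (factor 0.35), reflecting the reduced
day-to-day variability inside a persistent air mass and keeping both burst
days on the same side of the threshold.  Daily mean temperature is the
maximum minus a fixed 8 °C diurnal offset; vapour pressure is a uniform
0.35–0.85 fraction of saturation at the daily mean, hence positive and
never supersaturated.  Two lead-in days precede each May 1 so that the
consecutive-day rule and lags are defined on the first analysed day.

**Regions.** Rectangular blocks tile the grid; the first block is shrunk
off the cell lattice so its boundary cuts through cells (exercising
partial pixel fractions) while the others stay cell-aligned.  Each
region's ecumene is a rectangular sub-polygon covering 55–100% of its
area (the contract requires ≥30%).

**Counts.** Daily counts are negative-binomial in the NB2 shape
parameterised to mean μ and variance φμ (size r = μ/(φ−1), success
probability 1/φ), which reproduces the quasi-Poisson variance assumption
exactly at the moment level; φ = 1 falls back to Poisson, and φ < 1 is
rejected as unrepresentable.  The log-mean is α_s + β·x with one intercept
per stratum, α_s ~ Normal(log baseline, 0.5²).  The stratum intercepts
deliberately induce between-stratum confounding, so crude pooled rate
ratios are biased and recovery of β is a genuine test of the conditional
analysis.  Day totals are split multinomially into ~20 diagnostic
profiles (ICD-10 primary code plus, for external causes, a secondary
V/W code paired with an S/T primary, as real abstracts pair them), then
into age groups (45/25/30% across 0–4, 5–12, 13–18) and sex (50% M, 47% F,
3% missing).  Roughly 40% of events carry codes outside every named
outcome and count toward all-cause only.  One global seed is expanded into
named substreams (weather, regions, counts, humidity) so components are
independently reproducible.

**What the generator does not emulate.** Humidity–temperature coupling
beyond the saturation bound; topography, coastlines or urban heat islands;
weekday/holiday patterns in counts; reporting delays; within-stratum serial
correlation of counts beyond what the shared exposure induces; secular
trends across years.  Passing tests therefore demonstrate correctness of
the *method* under the stated data-generating assumptions, not robustness
to every artefact of registry data.

## Spatial aggregation

Weights are exact polygon–cell intersection areas (shapely), normalised to
sum to one per region; cells with zero overlap are absent rather than
zero-filled, an empty ecumene intersection raises a distinct signal, and a
missing cell value on any date is an error naming the date and cell rather
than a silent NaN.  The cell-centre alternative (counting a cell wholly in
or out) was rejected because exact fractions are deterministic and match
the pixel-fraction weighting the design calls for.  Relative humidity uses
Bolton's saturation approximation with the canonical constants 6.112 hPa,
17.67 and 243.5 °C, evaluated at the daily *mean* temperature, because
vapour pressure is a daily average and pairing a daily-average humidity
with the daily maximum would systematically understate RH.  Supersaturated
values (RH > 100) are retained, not clipped: they are informative for
quality control and clipping is irreversible.

## Exposure

Thresholds are empirical percentiles (linear interpolation between order
statistics) of daily maximum temperature pooled over all warm-season days
of all years per region.  Pooling, rather than averaging yearly
percentiles, is the default because it is the dominant convention in the
percentile-threshold heatwave literature; the year-averaged variant is
available via `compute_thresholds(..., method="by_year")`.  Exceedance is
strict (`>`): a tie at the threshold is not an exceedance.  Lead-in days
participate in the t−1 condition and in lags but are excluded from
percentile pooling and from the analysed frame, and exposure runs may span
month boundaries — exposure is physical and independent of the
stratification calendar.  Fewer than 100 pooled days per region triggers a
warning (thresholds unstable) rather than an error.  A lagged position
whose source date precedes the simulated series is set to 0 (unexposed),
the conservative choice.

## Outcome classification

ICD-10 ranges are closed intervals over three-character categories
compared lexicographically, so letter rollovers (S00–T66 containing T00)
work without enumeration; a bare code covers all of its subcodes, and
"T68-88"-style endpoints inherit the start letter.  "N00–N399" in the
renal definition is read as N00–N39, the urinary-system block, treating
the trailing 9 as a truncation artefact.  Drowning, falls and
transportation are matched in primary or secondary fields (external-cause
codes live in secondary fields); injury (S00–T66, T68–T88) is matched on
the primary code only.  Since T67 (heat) sits in the deliberate gap of the
injury range, heatstroke is never an injury.  The taxonomy ships as a YAML
resource and round-trips through serialisation.  Aggregation produces the
full region-day × outcome cross with explicit zeros, because zero days are
informative in count regression.

## Design and estimation

Strata are keyed by (region, year, month, ISO weekday); a weekday occurs 4
or 5 times in a month, giving each case day 3 or 4 controls.  The
count/exposure/weather join must be lossless: any missing region-day is an
error listing the keys, never a silent drop.  Strata with zero events or
no within-stratum exposure variation are removed before fitting — they
contribute a constant to the conditional likelihood, and removing them
changes neither the maximiser nor the likelihood value (asserted by test)
— but they would distort the dispersion degrees of freedom if retained.

The conditional likelihood is the multinomial form obtained by
conditioning on stratum totals.  Newton–Raphson starts from β = 0 with
step-halving; the objective is concave, so this is globally convergent and
fully deterministic.  Convergence requires max|score| < 1e-8 and relative
log-likelihood change < 1e-10 (the ascent check uses a rounding-aware
slack of 1e-10·|ℓ| so that float cancellation on large tables cannot
stall the line search); non-convergence within 100 iterations raises with
the iteration trace.  Rank deficiency after within-stratum centering is
detected by SVD and reported with the aliased column names.

Dispersion is φ = Pearson X²/(N − p − S) with fitted means μ̂_sj = n_s·p̂_sj,
counting the S eliminated stratum parameters in the degrees of freedom, as
in stratum-eliminated Poisson fitting.  φ is not floored at 1:
underdispersion is reported as found.  Confidence intervals are Wald on
the log scale with z = 1.959964; no small-sample correction.  The
humidity adjustment enters as a single linear term.  Reports carry a
`suppressed` flag when fewer than 20 events fall on exposed days; the
model is still fitted so diagnostics remain available, and suppression is
applied at the reporting level only.

Correctness of the estimator rests on two independent anchors: a
single-stratum closed form (1 exposed day with 4 events against 3 control
days with 6 gives RR = 2 exactly) and the equivalence, in coefficients and
unscaled covariance, with an ordinary Poisson regression carrying explicit
stratum dummies (statsmodels), checked to 1e-6 relative on random
instances.

## Problem sizes

The default synthetic frame is 10 seasons × 153 days × 9 regions
(13,770 analysed region-days; 3,150 strata) on a 12×12 km grid — ample for
every design property while keeping a full pipeline run in seconds.
Parameter-recovery checks use 500 strata × 200 replicates; exposure
brute-force checks use 10⁶ days; Monte-Carlo weight validation uses 10⁵
points.

## Known limitations

* Pearson-based φ is mildly biased downward when stratum means are small,
  so quasi-Poisson intervals can undercover slightly (the recovery checks
  report coverage near, occasionally just below, 95%); this is a known
  property of moment-based dispersion estimation at low counts, not of the
  conditional likelihood.
* Single-realisation pipeline estimates on the default frame rest on only
  ~50–60 informative strata at the 99th-percentile definition, so their
  intervals are wide; sensitivity definitions (97.5th, 95th) are much
  better powered, exactly as in real analyses of this design.
* Inputs are assumed to share one planar CRS; no reprojection is done.
* Area weighting, not population weighting, within the ecumene.
* No distributed-lag modelling and no event definitions longer than two
  days; lags are restricted to 1–2 days.
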