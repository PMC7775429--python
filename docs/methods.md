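# Methods

This note documents the statistical model behind `gridveg`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that affect results.

## The evaluation model

The premise: in water-limited, largely unmanaged landscapes, inter-annual
vegetation anomalies are driven by climate anomalies, so a gridded climate
product that represents the regional climate well should correlate with the
vegetation signal over most of the area — and a product that does not is
unlikely to correlate by accident once multiple testing is controlled.  The
correlation of climate features with NDVI peak anomalies therefore serves as
a proxy for product quality where no station data exist for direct
validation.

Both sides of the correlation are *anomalies*: a year's window-aggregated
value minus the across-year mean of that aggregate, so every series is
mean-zero by construction and the units of the underlying variables drop
out.  Window aggregation uses the mean rather than the sum; Pearson and
Spearman correlations are invariant to that choice, so nothing downstream
depends on it.

### Vegetation signal

Sub-monthly NDVI composites are reduced to monthly maxima (bucketed by the
composite's nominal start date), and the peak anomaly of year *y* is the
mean of the monthly maxima over the region's peak months (default
July–August, configurable per region) minus the across-year mean.  Using the
peak maximum avoids gap-filling choices, snow contamination outside the
growing season, and maximizes the weak vegetation signal of drylands.  The
annual series is screened for serial dependence with a Ljung–Box test
(lags = min(10, n/5), at least 1) plus ±1.96/√n bounds on the ACF; the lag
rule is this package's convention since no single standard exists at n = 18.

### Season windows

Six windows map monthly values to one value per year: hydrological year
(Jul(y−1)–Jun(y), the 12 months preceding the vegetation peak), winter
half-year (Nov–Apr), spring (Mar–May), the Feb–Mar transition, summer
(Jun–Aug) and spring–summer (Mar–Aug).  Every window also exists as a
two-year variant (mean of the aggregates of years *t* and *t−1* before
centering), capturing lagged vegetation response.  Snow variables are never
paired with the two summer-containing windows; the hydrological year remains
eligible for snow.  The two-year variant of a feature needs data for the
year before the first analysis year; if that pre-period is missing the first
year is dropped for that feature and recorded in the output metadata.
Partially invalid climate cells are not gap-filled: a year whose window
aggregate touches an invalid value is dropped from that feature with a
warning, and pixels invalid in every year are excluded outright.

### Snow metrics

The daily snow-index cube is taken on the 0–100 integer NDSI scale.  Pixels
with strictly more than 60 % invalid days over the whole series are
excluded; remaining gaps are filled linearly in day index, with leading and
trailing gaps copying the nearest observation.  Fractional snow cover is
`FSC = −0.01 + 1.45·NDSI`, truncated to [0, 100] % — the truncation bounds
are only reachable on the 0–100 scale, which is why that scale is the
default; equivalently the snow-cover-duration threshold "0.2" is interpreted
as 20 on this scale (both are config-overridable, `SnowConfig`).  SCD counts
days with NDSI strictly above the threshold per calendar month; NDSI and FSC
aggregate to monthly means.

### Dual-scale screen

Area scale: Pearson `r` between a feature's area-averaged anomaly and the
NDVI area anomaly, `p` two-sided from the `t` distribution with `n − 2`
degrees of freedom; Spearman applies the same approximation to midrank
correlations (a permutation option would be exact at n = 18 but the
asymptotic form is the documented default).  All features of a region form
one Benjamini–Hochberg family (`m` = catalog size) controlled at `q = 0.05`;
per-class analyses form their own families.

Pixel scale: the same Pearson test per analyzed pixel, summarized as the
percentage of pixels with raw `p ≤ 0.05`.  Pixel-level p-values are
deliberately not multiplicity-adjusted — the area-level FDR screen carries
the error control, and the pixel percentage is a descriptive coverage
measure; a flag switches on per-pixel BH for sensitivity analysis.  Pixels
with zero variance in either series are excluded from numerator and
denominator.  No spatial-autocorrelation or field-significance correction is
applied to the pixel maps; this is a known limitation, not an oversight.

A feature is **highly suitable** iff it is FDR-significant and at least
50 % of analyzed pixels are individually significant.  Reports are sorted by
the pixel percentage, descending.

### BCa intervals

Uncertainty of the area correlation is a 95 % bias-corrected and
accelerated bootstrap interval from 2500 pairwise resamples.  The bias term
is `z0 = Φ⁻¹(#{r*_b < r̂}/B)` with ties counted half; the acceleration uses
the third-moment formula on empirical influence values, estimated by
default from the linear regression of the bootstrap replicates on the
centered resampling frequencies (minimum-norm least squares).  The
regression estimate is the convention of the classic bootstrap packages and
reproduces their endpoints on shared fixtures; a leave-one-out jackknife
estimate is available via `accel="jackknife"` and gives slightly narrower
lower tails.  Endpoints are read at the BCa-adjusted percentiles with
order-statistic interpolation on the normal-quantile scale and clamped to
[−1, 1]; a degenerate bootstrap distribution collapses the interval to the
point estimate with a warning.

Known property: for Pearson correlations at n = 18 and ρ ≈ 0.7 the true
coverage of the nominal 95 % BCa interval is ≈ 93 % (measured here by
simulation with this implementation, with scipy's, and with the classic R
implementation — all agree).  The interval is therefore mildly
anti-conservative at this sample size; the acceptance suite checks coverage
against the 93–97 % band.

### Stability assessment

*Stepwise*: years are partitioned into 3 folds, 100 times with seeded
shuffles; on each training set the feature with the largest |Pearson r| is
recorded (ties break by catalog order, an explicitly arbitrary choice), and
selection percentages are tallied over the 300 fold fits.

*Shadow-feature importance*: each iteration appends an independently
shuffled shadow copy of every kept feature, fits a random-forest regression
(500 trees, `ceil(F/3)` candidate features per split, minimum node size 5 in
the classic sense — nodes of ≤ 5 cases become terminal, children
unconstrained; constraining leaf sizes instead makes 18-sample trees far too
shallow and blurs the importance ranking), and scores every column by
out-of-bag permutation importance normalized to a z-score over trees (mean
error increase divided by its standard error).  A real feature scores a
*hit* when its z exceeds the best shadow z.  After each iteration, one-sided
binomial tests of the hit count against Binomial(iterations, ½) at
α = 0.05 confirm (upper tail) or reject (lower tail) features, without
additional multiplicity adjustment; rejected features leave the design,
confirmed ones keep competing, and whatever is undecided at the iteration
cap (500) is tentative and counted as not confirmed.  The whole run is
repeated (500 by default) with seeds derived from one master seed via
`SeedSequence`; reports give the confirmation percentage and the mean
importance over confirming repetitions.

Caveat worth knowing: with strongly correlated features — and the window
catalog necessarily contains nested siblings, e.g. the winter half-year is
six of the hydrological year's twelve months, giving a true inter-feature
correlation near 0.7 — the forest importance splits across the siblings, and
at 18 years the top-ranked feature can flip between them from world to
world.  The marginal-correlation ranking is considerably more stable than
the importance ranking in this regime.

## The synthetic world

`make_world` generates: (1) i.i.d. standard-normal latent monthly anomalies
per climate variable; (2) product cubes = seasonal climatology + fidelity ×
latent + residual noise split between a year-persistent bias (which survives
window averaging — this is what makes a product genuinely corrupted at the
interannual scale) and purely monthly noise (which mostly averages out),
plus per-cell spatial noise, on each product's coarse grid; a fidelity of
zero yields the pure-noise product; (3) a planted driver signal `a_t` =
scaled mean of the latent months inside the planted window (so the planted
window is by construction its cleanest measurement, and sibling windows
correlate with it only through month overlap); (4) an NDVI cube whose
peak-month anomaly per pixel is `gain · (a_t · coupled + η_t + ε_it)` with
the response zeroed in a contiguous valley band covering 20 % of rows
(riparian class, emulating irrigation/groundwater decoupling); (5) a daily
NDSI cube with a seasonal curve, winter anomalies tied to the driver's
winter months, Markov-persistent cloud gaps (stationary missingness rate
0.25, mean run length 3 days) and a couple of pixels forced over the
exclusion rule; (6) a band-structured class raster (non-vegetated /
alpine grassland / dwarf-shrub steppe / riparian).

The shared-residual SD `σ_a` is solved from the correlation identity
`r² = c²s² / (c²s² + σ_a² + σ_p²/N)` (c = coupled fraction of analyzed
pixels, s = realized SD of the drawn signal, σ_p = pixel noise SD = 0.6,
N = analyzed pixels), so the planted area correlation is centered on the
target *conditionally on the drawn signal*; infeasible targets raise with
the attainable bound.  At effect size 0 there is no response and the shared
residual defaults to a small value (0.15), reflecting that a null world's
vegetation anomaly is dominated by pixel-local noise.

What the generator does **not** emulate: physically realistic climate
fields (no orography, no seasonally varying circulation), spatially
correlated NDVI noise, sensor artifacts, land-use change, or phenological
shifts.  Passing tests on these worlds demonstrate that the statistical
machinery is calibrated and recovers planted structure; they do not certify
performance on real imagery with spatially structured errors.

## Numerical conventions and degenerate inputs

* Standardization divides by the across-year SD with ddof = 1; constant
  series raise.
* Anomaly series are exactly mean-zero (checked to 1e-8); years must be
  contiguous after drops.
* Nearest-neighbor regridding assigns by target-pixel-center falling inside
  a half-open source cell `[edge, edge)`, so ties are impossible and every
  output value equals exactly one input value.  Cubes are assumed
  pre-projected to a common CRS; the CRS is an opaque pass-through label.
* Correlation of a zero-variance series raises a dedicated error; |r| = 1
  returns p = 0 exactly.
* The BH step-up is hand-implemented and cross-checked against both a
  brute-force largest-k search and statsmodels.
* Reported CSVs round for display (p to 4 decimals, r/CI to 2, pixel % to
  integers) and carry the unrounded values in parallel columns; identical
  config + seed reproduce every artifact byte for byte.

## Problem sizes used by the test suite

The shipped tests and the acceptance script use scaled problem sizes chosen
to exercise every code path at desk scale: worlds of 16×16 to 110×110 NDVI
pixels, 18 years, catalogs of 36–72 features, 2000 null catalogs for the FDR
calibration, 1000 datasets × 2500 resamples for the BCa coverage check, 50
worlds for planted-driver recovery with the shadow-feature procedure capped
at 50 iterations and 150 trees, and reduced repetition counts for the
end-to-end determinism check.  The statistical defaults in the library
(2500 bootstrap replicates, 100×3 stepwise, 500×500 shadow-feature runs)
remain the full-scale settings.
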