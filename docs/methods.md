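# Methods

This note records the statistical model, the defaults and the design
choices behind `disttrend`, and what the synthetic validation does and
does not demonstrate.

## Survey model and simulator

The generator emulates stratified seasonal line-transect surveys of
clustered animals. Within each transect × occasion, the number of
clusters present in the observable strip of half-width `w_max` is
Poisson with mean `2·w_max[km]·L·D_c`, where `D_c` is the true cluster
density — i.e. clusters are placed as a homogeneous Poisson process, the
spatial-uniformity assumption the distance-sampling estimator itself
relies on. Perpendicular distances are uniform on `[0, w_max]` and each
cluster is detected independently with probability `exp(−x²/2σ²)`, so
detected distances follow the half-normal truncated at `w_max`.
Distances are continuous in metres (rangefinder-style measurement; no
rounding or measurement error). Cluster sizes are `1 + NegBin(mean−1,
dispersion)`, which guarantees sizes ≥ 1 with exact mean control, or a
point mass; detection is independent of cluster size.

True density is `base_cluster_density × trend(year) ×
season_multiplier(season) × mean cluster size`. Trends are constant,
linear (proportional change per year, floored at 0) or smooth
(geometric, `(1+m)^Δt`). Season multipliers model migration, e.g. a
dry-season concentration factor > 1 and a rains factor near 0.

Seeding: one master seed; each area × species × occasion draws from a
substream derived from a CRC of its labels, so outputs are independent
of iteration order and single strata can be re-simulated in isolation.

The reference scenario encodes a six-unit, four-species programme with
schedules of 24/24/7/12/24/24 seasonal occasions over 2011–2019, one
unit surveyed by a single long transect, one sparse unit analysed
season-aggregated, a negative-control unit with zero/near-zero
densities, and dry-season concentration of the migratory grazers in one
park. Base densities (0.05–2 clusters km⁻²), detection scales
(140–200 m) and cluster-size means (3–10) were chosen once to give
detection-fit sample sizes mostly above the recommended 60 while keeping
a couple of sparse series that exercise the warning paths.

What the simulator does **not** emulate: non-random transect placement
along roads (and road attraction/avoidance), responsive movement before
detection, size-biased detection, spatial autocorrelation, and
measurement error. Passing recovery tests therefore show the estimator
chain is internally correct under its own assumptions, not that those
assumptions hold for any particular field programme.

## Detection function and density estimation

- Truncation: `w` is the empirical `1−fraction` quantile
  (linear-interpolation convention); distances strictly greater than `w`
  are dropped. Default fraction 0.10.
- Likelihood: exact continuous-data likelihood of
  `f(x) = g(x)/∫₀ʷ g`, with the half-normal key and cosine adjustments
  of orders {2}, {2,3} as candidates against the key-only fit, selected
  by AIC. `σ` is optimised on the log scale (Brent for the key-only
  1-D problem to ~1e−11; L-BFGS-B with tight tolerances otherwise);
  `∫₀ʷ g` uses fixed 64-point Gauss–Legendre quadrature, so fits are
  deterministic. With `w = inf` the untruncated key-only model is
  fitted, whose MLE is the closed form `σ̂² = Σx²/n` — used as the
  oracle check of the numerical path.
- Constraints: a candidate is rejected (not returned) if `g` is
  negative anywhere on `[0, w]`, or — for adjustment candidates — if `g`
  is not monotone non-increasing. Monotonicity is the standard
  constraint for adjustment-term fits; without it, narrow-`w` fits at
  n ≈ 100 occasionally produce runaway `P̂` values, which degrades
  interval calibration (measured ~90% coverage without the constraint
  vs ~94% with it).
- Fewer than 60 sightings triggers a warning, not a failure; fewer than
  2 distinct distances means no fit, and all of that area × species'
  strata are reported as zero-density rows (there is nothing to correct
  for detection when there are no usable sightings).
- Variance: CV²(D) = CV²(n/L) + CV²(P̂) + CV²(s̄). The encounter-rate
  component uses the classic effort-weighted between-transect estimator
  `var(n/L) = K/(L²(K−1)) Σ l_k²(n_k/l_k − n/L)²`, with a Poisson
  fallback (`var(n) = n`) for single-transect strata. CV(P̂) comes from
  the observed information matrix (central-difference Hessian of the
  negative log-likelihood) via the delta method; CV(s̄) is the sample
  CV of cluster sizes divided by √n. 95% intervals are log-normal:
  `[D/C, D·C]`, `C = exp(1.96·√ln(1+CV²))`.
- Post-stratification: the pooled (all seasons, all years) detection
  function of each area × species is applied to every season-year
  stratum; mean cluster size is the within-stratum mean (undefined for
  zero-sighting strata, whose density is 0 with CI [0, 0]).
- Repeated surveys within a season: effort summed per transect,
  sightings concatenated, before estimation.

## Trend analysis

Stage 1 recovers each estimate's SD from its interval,
`SD = (U−L)/(2·1.96)`, and draws `n_rep = 1000` replicates: truncated
normal on `[L, U]` for non-zero estimates, plain normal for zero
estimates (a zero-width interval degenerates to a constant — the
zero-density case reproduces exactly).

The smoother is a penalized cubic regression spline of density on year
with basis dimension k = 4, fitted to all stacked replicate points (one
smoother per series; fitting one model per replicate is a documented
alternative reading, not implemented since the stacked fit uses the
identical point set). With k = 4 there are no interior knots, so the
basis spans exactly the cubic polynomials — which yields an exact
equivalence test against OLS cubic regression at zero penalty. The
penalty is the integrated squared second derivative (null space =
straight lines), computed exactly by Gauss quadrature; the smoothing
parameter minimises GCV `n·RSS/(n−edf)²` over a log grid (1e−7…1e7,
plus 0 when the data support an unpenalized fit) on the year axis
rescaled to [0, 1]. Prediction standard errors use the Bayesian
covariance `σ̂²(XᵀX+λS)⁻¹` with `σ̂² = RSS/(n−edf)`, matching common GAM
practice; the test suite cross-checks predictions and SEs against R's
mgcv on the same data. Series with two distinct timepoints fall back to
an unpenalized straight line (logged); one timepoint is skipped with a
warning.

Stage 2 draws, per predicted year, `n_rep` values from
`N(D̂_predicted, SE)` where SE is the standard error of the predicted
mean (not a prediction interval — the resampling propagates model
uncertainty, not residual scatter). The per-year mean of draws is the
trend line; the 2.5/97.5 percentiles form the plotting ribbon
(percentile rather than ±SE ribbons — a display choice). Negative
draws and predictions are retained in all computations and clipped only
in plots.

Predictions are made at integer years from the floor of the first to
the floor of the last observed timepoint. Season-aggregated series
place each survey at a decimal year using fixed season offsets
{LR: +0.25, Dry: +0.58, SR: +0.92}, matching the seasons' calendar
positions.

Seeding mirrors the simulator: master seed → per-series substream (CRC
of the series key) → per-stage substreams, so results are reproducible
and independent of input row order.

## Change summaries

Percent change `100·(final−initial)/initial` is computed on two-year
window means of the stage-2 trend line (the modeled series, not the raw
estimates), with the ratio taken after averaging the trend line. By
default the windows are each series' first two and last two predicted
years; `reference_windows()` encodes the reference scenario's calendar
(short rains 2011–2012 → 2018–2019, long rains 2012–2013 → 2018–2019,
dry 2012–2013 → 2017–2018 since the final year has no dry-season
survey, the short series 2012–2013 → 2014–2015, the aggregated unit
2011–2012 → 2017–2018). A zero initial density yields an undefined
(NaN, logged) change, never ±inf.

## Problem sizes in the validation battery

The acceptance script and test suite use: 20 random draws for the
closed-form MLE oracle; 200 simulated surveys (50 × 2 km transects,
true density 10 animals km⁻², σ = 100 m) for estimator bias; 500
surveys (~90–100 sightings each) for CI coverage; 500 simulations of
n = 150 for KS type-I error; 50 simulated nine-year series (CV 0.2)
each for linear (+50%) and null trend recovery; and one full run of the
reference scenario (≈ 6,500 sightings, 460 strata, 64 series). These
sizes give Monte-Carlo standard errors comfortably inside the asserted
bands while keeping a full run in the tens of seconds.

## Known limitations

- No covariate detection functions, hazard-rate/uniform keys, or
  size-bias corrections; one pooled detection function per
  area × species is assumed adequate.
- Truncation `w` is treated as fixed in the variance, as is standard;
  the variability of the estimated 90% quantile is not propagated.
- The GCV-selected smoothing parameter differs in general from mgcv's
  (different basis and grid); agreement is close but not exact.
- Percent-change uncertainty is summarised only through the trend-line
  ensemble; no formal test of change is provided.
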