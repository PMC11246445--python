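# disttrend

Line-transect distance-sampling density estimation and two-stage
Monte-Carlo trend analysis for seasonal wildlife monitoring programmes.

`disttrend` is aimed at ecologists running repeated road- or
foot-transect surveys of large herbivores across several management units
(parks, community conservation areas, control sites) who want
area-, species- and season-specific density time series with honest
uncertainty, smooth multi-year trend lines, and simple percent-change
summaries — plus a synthetic survey generator with known truth so every
stage of the pipeline can be validated by parameter recovery.

## The model

**Detection and density.** Perpendicular sighting distances x on a
transect are modeled with a half-normal detection function with cosine
adjustments,

    g(x) = exp(-x² / 2σ²) · [1 + Σⱼ aⱼ cos(jπx/w)],   g(0) = 1,

fitted by maximum likelihood to unbinned distances after truncating the
farthest 10% (w = the 90% quantile). One detection function is fitted
per area × species, pooled across seasons; the number of cosine terms is
chosen by AIC, subject to g being non-negative and non-increasing, and a
Kolmogorov–Smirnov test checks goodness of fit. Density for each
season-year stratum j of area i is then

    D_ij = n_ij / (2 w L_ij P̂),

where n_ij is the stratum's detection count, L_ij its summed transect
length, and P̂ = (1/w)∫₀ʷ g(x)dx the average detection probability
(so wP̂ is the effective strip half-width). Cluster density is scaled to
animal density by the stratum's mean cluster size. The CV combines
encounter-rate, detection and cluster-size components; 95% confidence
intervals are log-normal.

**Trends.** For each series, stage 1 draws 1000 replicate densities per
estimate from a truncated normal on [L, U] with
SD = (U − L)/(2·1.96) (plain normal for zero estimates); a penalized
cubic regression spline s(Year, k = 4) is fitted to the stacked
replicate points with the smoothing parameter chosen by GCV. Stage 2
draws, per predicted year, 1000 values from N(D̂_predicted, SE); their
mean is the trend line. Percent change is
100 · (final − initial)/initial on two-year window means of that line.

## Worked example

The built-in reference scenario simulates a six-unit, four-species
monitoring programme (unequal schedules of 24/24/7/12/24/24 seasonal
surveys, one negative-control unit, one sparsely surveyed unit analysed
season-aggregated, strong dry-season concentration of migratory
grazers):

```
$ disttrend all --seed 1 --out-dir demo
pipeline complete in 2.1s: 460 strata, 64 series -> demo
```

`demo/density.csv` holds one row per area × species × season-year
stratum, e.g.

```
area,species,year,season,n,effort_km,w_m,p_hat,...,density,se,cv,ci_low,ci_high
BWMA,elephant,2011,SR,15,83.8,322.3,0.655,...,1.412,0.373,0.264,...
```

and `demo/change_summary.csv` condenses each fitted series, e.g. for
zebra (truth: constant densities everywhere; a strong seasonal
concentration in TNP):

```
area species season initial_years final_years  initial_density  final_density  percent_change
 TNP   zebra    Dry     2012-2013   2017-2018        45.902932      41.134848      -10.387319
 TNP   zebra     LR     2012-2013   2018-2019         4.147737       1.347565      -67.510825
RWMA   zebra    Dry     2012-2013   2014-2015         2.664068       2.268009      -14.866717
```

The dry-season density in TNP (~46 animals km⁻²) versus the long rains
(~4) reflects the simulated migration; percent changes scatter around 0
because the true zebra trend is constant, with wider swings in the
sparse, low-density series where the confidence intervals are widest.
`disttrend all --plots` additionally writes one figure per series
(points with 95% CIs, percentile ribbon, trend line).

The same subcommands work stepwise on your own delimited tables:
`disttrend simulate | estimate | trend | summarize` (see `--help`;
sighting tables need area, species, year, season, transect_id,
distance_m, cluster_size; effort tables area, year, season, transect_id,
length_km).

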