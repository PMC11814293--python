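# Methods notes

These notes document the models behind `mudflat`, the defaults and why they
were chosen, and what the synthetic-data tests do and do not demonstrate.

## The monitoring problem

A synoptic benthic survey revisits thousands of intertidal stations every
year to estimate the abundance (ind m⁻²) and biomass (g ash-free dry mass,
AFDM, m⁻²) of macrozoobenthic taxa, together with sediment composition. The
statistical core is threefold: a spatial sampling design that serves mean
estimation, mapping, and autocorrelation estimation at once; a laboratory
processing chain that turns raw core contents into standardized densities;
and a quality-control/imputation layer that completes missing biomass
measurements from biomass–length allometry.

## Synthetic worlds

`worldgen` simulates the landscape the downstream analysis assumes:

* **Latent densities.** Per species, log density is a stationary Gaussian
  random field with exponential covariance C(h) = σ²·e^(−h/r); the density
  surface is its exponential (log-Gaussian), so densities are positive and
  right-skewed as benthic counts are. Fields are simulated exactly by
  Cholesky factorization of the covariance at the requested cell centers or
  points; factors are cached per geometry, making Monte-Carlo replication a
  matrix-vector product per draw. The raster surface carries the structured
  component; the nugget is interpreted as micro-scale noise and is realized
  only when station values are drawn.
* **Sampling.** Counts per visit are Poisson(density × core area); each
  individual receives a lognormal length (the length law is a modelling
  choice — real length distributions are not specified anywhere); lengths
  below the 1-mm sieve mesh are discarded, which is exactly the thinning the
  field protocol applies.
* **Subsampling.** Taxa flagged subsampling-eligible are subsampled when a
  visit yields more than 100 retained individuals (the protocol literature
  states subsamples of about 30 individuals at high density but no trigger;
  100 is our operational choice). The recorded fraction is f = 30/count and
  each individual is kept with probability f, making the corrected count
  n_kept/f unbiased for the true count — the property the tests verify.
* **Masses and missingness.** AFDM = a·L^b·e^ε with ε ~ N(0, σ_m²);
  defaults a = 10⁻⁵ g, b = 3, σ_m = 0.15 (σ_m matches the residual spread a
  well-behaved species curve shows). Lengths and masses are deleted with
  configured probabilities; "broken" individuals keep only a shell-top or
  shell-bottom width, from which length is later re-estimated.
* **Sediment.** Each station draws a grain-size spectrum from a two-mode
  lognormal mixture — a mud mode (median 15 µm) and a sand mode centred on
  the local median-grain-size field — weighted by the local mud-fraction
  field and binned onto the 126 geometric classes from 0.04 to 2000 µm,
  with multinomial (particle-counting) noise.

What the generator does **not** emulate: tidal hydrodynamics, sediment
transport, inter-annual population dynamics (years are independent redraws),
species interactions, and the real coastline geometry (worlds are
rectangles; the intertidal mask is a thresholded smooth field). Passing
tests therefore demonstrate the *procedures* are correct under the stated
stochastic model, not that the model captures every feature of real
mudflats.

## Sampling design

Grid stations sit on a square lattice (spacing 500 m, random origin offset)
clipped to the intertidal mask; random stations are drawn uniformly over the
total gridline length inside the mask (uniform-over-length is the
maximum-entropy reading of "random positions on gridlines") until the random
share of all stations is as close as achievable to the target (default 20%,
defined as random/total). Yearly maintenance deactivates drowned stations —
identifiers are permanent and never reused — adds stations on newly
emerged lattice nodes, and rebalances the per-basin random share to within
two percentage points.

`evaluate_designs` compares five layouts (simple random, grid, two transect
variants, grid+random) with *equal station counts* — unequal counts raise a
fairness error. The transect geometries are our own: parallel lines 2× and
4× the grid spacing apart with along-line spacing chosen to preserve the
grid's station density, so equal n is achievable on the same extent.
Comparisons use common random numbers: one field realization per replicate,
simulated jointly over the union of all layouts, so design differences are
paired and not drowned in Monte-Carlo noise. Metrics per design and
autocorrelation level (e-folding range 0 = pure nugget, 250, 500, 1000 m —
bracketing the 500-m spacing; only orderings between designs are asserted,
since absolute biases depend on the generator):

* minimum detectable difference, MDD = (z₀.₉₇₅ + z₀.₈)·σ̂·√(2/n), i.e. a
  two-sample test at α = 0.05 and power 0.80;
* mean absolute kriging error at held-out points;
* bias of the fitted variogram range.

Design evaluation operates on the latent Gaussian field values at stations;
Poisson observation noise would enter all designs identically and only
dilute the contrasts of interest.

## Laboratory rules

* Counting: fragmenting polychaetes count heads (plus wholes) from the
  heads-only era (2011, configurable); before that, max(heads, tails) +
  wholes — the max avoids double-counting one fragmented animal, which the
  historical "loose heads and tails" bookkeeping leaves ambiguous.
  Whole-only taxa (the tube worm *Lanice conchilega*) ignore fragments.
* Standardization: abundance m⁻² = count / subsample fraction / core area,
  with the boat (0.0173 m²) and walk (0.0177 m²) areas; biomass identically.
* Razor-clam lengths: L = 6.5·width_top or 6.6·width_bottom, flagged as
  estimated so curve fitting can exclude them.
* Sediment: mud % sums the classes fully below 63 µm plus a log-linear split
  of the straddling class; the median grain size is the log-linear
  interpolation of the cumulative volume curve's first crossing of 0.5.
  Classes are geometric because laser-diffraction instruments report
  log-spaced bins.

## Allometry, outliers, imputation

The biomass–length relationship is smoothed by LOESS with span 0.6 and
local degree 2 (the classical definition; our implementation reproduces R's
`loess(..., surface="direct")` to machine precision, which a unit test
asserts). Two numerical choices are ours, both flagged openly:

* mass is fitted on the log scale — it spans orders of magnitude and a
  single residual IQR fence is only meaningful with stabilized variance;
* length also enters on the log scale by default, so a clean power law
  m = a·L^b is locally linear and recovered without boundary bias (on raw
  length, span-0.6 local quadratics leave up to ~20% bias at the short-length
  edge). Both scales are switchable (`log_mass`, `log_length`).

Outliers are residuals outside [Q1 − 2·IQR, Q3 + 2·IQR]; quartile-anchored
fences are the standard Tukey construction with k = 2 (the alternative
reading, median ± 2·IQR, is noted but not used). On clean Gaussian
residuals these fences flag ≪ 1% of records. One removal pass and one refit
(iteration count is unspecified in the protocol; one pass is the
conservative choice). Fewer than four records leave quartiles undefined:
nothing is flagged, with a warning.

Imputation is hierarchical. For a record of a given taxon, record pools are
nested season (all years pooled) ⊃ year ⊃ year+region ⊃ year+basin; "region"
is a configurable grouping of basins, defaulting to a west/east split. The
finest pool holding ≥ 75 complete records (≥ 45 for taxa predominantly under
11 mm) provides the LOESS curve; records without a usable length fall back
to the pool mean at ≥ 30 records; method-25 taxa pool prior years instead.
Predictions are clamped to the training length range (no extrapolation) and
floored at zero; every imputed value carries a method code (24 curve,
12 mean, 25 historical mean) and scale in an audit table that is written
*next to*, never into, the published biota file.

## Correlograms and kriging

The correlogram is derived from the Matheron semivariogram,
ρ(h) = 1 − γ̂(h)/s²; a per-distance-class Moran's I estimator is available
as an alternative label. Default lag bins: 10 bins of width spacing/2 up to
5× spacing. Bins with fewer than 10 pairs are flagged unreliable. The
exponential variogram γ(h) = c₀ + c·(1 − e^(−h/r)) is fitted by least
squares weighted by pair counts; r is the e-folding distance (practical
range ≈ 3r), deliberately the same parameterization the generator uses so
range recovery is a well-posed round trip. A fit whose structured component
is negligible against the nugget flags the range unidentifiable rather than
reporting a meaningless number.

Ordinary kriging solves the standard (n+1) system with a Lagrange
multiplier, which enforces unit weight sums by construction (checked to
1e-8 in tests) and exactness at stations when the nugget is zero. Maps are
produced at 25-m resolution by default; cells farther than three ranges from
any station are flagged low-confidence. A singular system degrades to
nearest-neighbour with a warning. A log1p transform is available for skewed
density fields; back-transformed surfaces are biased low by Jensen's
inequality, which callers should note when integrating totals.

## Data model

The three CSVs carry exactly the published columns; missing values are
empty fields (configurable token). Absences are not stored in the biota
table — zeros are reconstructed by the `zero_fill` join, which emits exactly
|samples| × |taxa| rows and conserves totals. Percentages in campaign
summaries are rounded half-up to integers to match the printed table; the
averages row defaults to the 2008–2019 window, which is the convention the
printed averages actually follow (the alternative "all years but the
disrupted 2020 season" is selectable via `exclude_years` and gives different
totals). The packaged `campaign_totals.csv` is the printed per-year summary
shipped as a test fixture.

## Problem sizes and tolerances

Simulation-backed checks run at sizes chosen to make their Monte-Carlo error
small against the asserted margins: 200 replicates of 200 stations for the
design comparison, 50 fields of 400 stations for range recovery (median
within ±30%), 1000 stations for the unbiasedness checks (3 standard errors),
and the full 121⁴ ladder enumeration for the scale selector. Numerical
tolerances: kriging identities to 1e-8, the noiseless variogram round trip
to 1e-3, LOESS against R to 1e-8. Recovery tolerances are set by the
generator's own parameters; no external dataset is consulted.

## Known limitations

* The local tangent-plane lon/lat conversion is adequate at basin scale but
  not for geodetic work.
* Kriging is isotropic and covariate-free; tidal flats are anisotropic in
  reality (channels), so mapped surfaces should be read accordingly.
* The imputer fits models lazily per (taxon, scale, stratum) on first use;
  very wide multi-year tables may prefer a precomputed bank.
* The generator draws years independently; trend-detection power on real,
  temporally correlated data will differ from the synthetic setting.
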