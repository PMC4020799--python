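# Methods

`pengdisp` implements a presence / pseudo-absence habitat-modelling
pipeline for post-fledging dispersal of satellite-tracked king penguins,
together with the Argos track processing that feeds it and a synthetic
study generator that makes the whole chain testable without the
(undeposited) original tracking data and satellite layers.

## Track processing

Argos fixes carry a location class 0–3 with nominal accuracies of
>1 km, <1 km, <350 m and <150 m. Transmitters ran a 4 h on / 20 h off
duty cycle switched on at 01:00 GMT; a *duty cycle* is therefore
operationalized as the 24-hour window starting at 01:00 GMT, and any fix
(including ones received outside an on-window, which happens in real
data) is binned by that clock. Within each bird × cycle group the
highest class wins, ties going to the earliest fix; the survivor is the
*daily position*.

Migratory parameters per bird:

* **duration** — whole days from the deployment date to the date of the
  last transmission. This convention reproduces the published duration
  of every one of the 18 birds in the 2007 cohort exactly (deployments
  11 Dec 2007 at Volunteer Beach, Falkland Islands; 13 Dec 2007 at
  St Andrews Bay, South Georgia — the fieldwork spanned 13/14 Dec but
  only the 13th reproduces all eight South Georgia durations).
* **maximum distance to colony** — the largest great-circle distance
  from any daily position to the natal site.
* **minimum distance covered** — the sum of great-circle distances
  between consecutive daily positions; a lower bound on true path
  length.
* **mean / sd / maximum daily distance** — statistics of those
  consecutive segments. When daily positions are missing the segment
  still counts as one "daily" distance regardless of the gap; the
  per-bird position count is reported so gappy tracks are visible.

Distances are haversine on a sphere of radius 6371 km; the ~0.3%
sphericity error is far below the ≥1 km positional error of class-0
fixes. Cohort statistics use the arithmetic mean and the sample (n−1)
standard deviation; with a single bird the sd is reported missing, not
zero.

## The analysis lattice and environmental stack

The grid spans the geographic limits of the tracking data, 10°W–110°W ×
40°S–75°S, at 0.04° (≈4 km²) cells — 875 rows × 2500 columns, row-major
from the north-west corner. Cells are half-open boxes (west edge and
north edge belong to the cell) so every point maps to at most one cell.

Eight candidate covariates enter the models: bathymetry (BAT, m, stored
as positive depth), chlorophyll-a (CHLa, mg m⁻³), sea-surface
temperature (SST, °C) and sea-surface height (SSH, cm), each with a
local gradient (suffix `.G3`). Monthly fields are averaged cell-wise
over the modelling window (missing months skipped per cell), finer
rasters are aggregated by averaging source pixels whose centers fall in
a cell, and gradients are the *proportional change*

    PC = (max − min) × 100 / max

over the 3×3-cell moving window, computed on raw (unstandardized)
values. Numerical conventions: the window is truncated at grid edges
(no padding), missing neighbours are ignored, a flat window gives 0, an
all-zero window gives 0 (the 0/0 case), and negative inputs are
rejected with instructions to shift first — every covariate here is
non-negative, and the statistic is meaningless across a sign change.
PC is scale-free (invariant to positive rescaling) and bounded in
[0, 100].

All eight layers are then standardized to mean 0, sd 1 (n−1 denominator)
over non-missing cells, with the (mean, sd) pairs recorded for inverse
mapping. Pairwise Spearman rank correlations are reported, flagging
|rs| > 0.5; the screen is diagnostic only — nothing is dropped
automatically, since stepwise selection operates on the full candidate
set.

## Occurrence design

Daily positions between 1 January and 31 March 2008 are rasterized to
presence cells (binary per cell over the whole window; duplicates
collapse). "Surveyed area" is operationalized as every grid cell with
complete data for all candidate covariates — models cannot use
incomplete cells anyway, and no survey polygon exists. Pseudo-absence
candidates are those cells minus a 3×3-cell mask around every presence;
each of the 100 sets draws exactly as many cells as there are presences,
uniformly without replacement within a set and independently across
sets. No additional buffer is applied around the colony itself.

## The replicate GLM ensemble

Presence/absence in a cell is modelled by a binomial GLM with a logit
link on the standardized covariates (main effects only — the selected
models contain no interactions or polynomial terms). Terms are chosen
by backward-forward stepwise search minimizing AIC from the full
8-term model: at each iteration every single-term deletion and addition
is scored and the best strictly-improving move taken. Exact AIC ties
break toward the smaller model, then lexicographic term order.

Replicate r (r = 1…100) pairs the fixed presence cells with
pseudo-absence set r — a balanced design — and splits each class 70/30
into training and validation, redrawn per replicate as a disjoint
partition (train and test never overlap). Selection runs on the
training 70%; the selected model scores the held-out 30% and its
discrimination is the rank-based (Mann–Whitney) AUC, ties counting ½.
The ensemble reports mean AUC ± its standard error sd/√n across
converged replicates, marks the model *usable* when mean AUC ≥ 0.7, and
tallies how often each term is selected and with which sign. Replicates
whose GLM does not converge (complete separation drives the likelihood
to 0 and coefficients to infinity; both symptoms are checked) are
excluded from summaries and counted rather than silently included.

Competing models are the unique specifications visited by the search,
refitted on the same data, restricted to ΔAIC ≤ 2 of the best, sorted
best-first, with Akaike weights wᵢ = exp(−Δᵢ/2)/Σⱼ exp(−Δⱼ/2) over the
retained set. The table reports the full-data refit AIC; the replicate
AUC distribution is reported separately rather than conflated with it.

## Mapping

The most parsimonious model — by default refit on all presences plus
pseudo-absence set 1 — is projected over every cell as the inverse
logit of its linear predictor. Cells with any covariate missing, or
outside the model's environmental space (the per-covariate
[train-min, train-max] box — the simplest envelope consistent with
masking extrapolation), are masked. The probability surface is reduced
to three classes: low < 0.33 ≤ medium ≤ 0.66 < high, both 0.33 and 0.66
belonging to *medium*. Rasters are written to NetCDF with the grid's
georeferencing (probability as float64 with no fill-value rewriting, so
round trips are bit-exact; categories as uint8 with
masked/low/medium/high = 255/0/1/2).

## Synthetic study generator

The generator emulates the study conditions, not the Southern Ocean:

* **Environmental fields** — Gaussian-smoothed white noise rescaled
  linearly to each variable's observed range (BAT 0–7958 m, CHLa
  0–24.91 mg m⁻³, SST 0–21.32 °C, SSH 46.30–51.29 cm), with the kernel
  sigma (in cells) setting the spatial correlation length; sigma 0
  yields white noise. Monthly realizations are independent. The grid
  is treated as all-ocean: no land, coasts, fronts, currents or sea ice,
  so the fields have realistic ranges and smoothness but none of the
  structured gradients (shelf breaks, the Antarctic Polar Front) that
  make real covariates spatially confounded.
* **Movement** — a daily-step biased correlated random walk: lognormal
  step lengths with mean 45 km (the cohort's observed mean daily
  distance) and sd 25 km, von Mises directional persistence, and
  candidate destinations scored by exp(bias × suitability). This is a
  stand-in for dispersal, not a behavioural model of penguins.
* **Observation** — per day, 1 + Poisson(3) fixes uniformly inside the
  4-hour on-window; each draws a location class and isotropic Gaussian
  noise whose RMS displacement equals the class error scale (1.5, 1.0,
  0.35, 0.15 km for classes 0–3). Default class probabilities
  (0.17/0.28/0.30/0.25) were set so ≈98.6% of daily best positions are
  class 1 or better, matching the cohort's reported fix quality.
* **Occupancy ground truth** — a logistic model on the standardized
  covariates (default: BAT +1, SST −1, CHLa +1, intercept 0 — affinity
  for deep, cool, productive water at |β| = 1). For parameter-recovery
  experiments presence cells are drawn directly with probability
  proportional to suitability, because a finite biased walk samples
  occupancy only approximately; the walk-based route is exercised
  end-to-end with qualitative assertions (visited suitability exceeds
  the grid mean) instead of exact coefficient recovery.

Everything is deterministic given a seed (numpy `SeedSequence`
children per bird/month/stage), and all generated values stay inside
their configured ranges by construction.

Because the synthetic fields are independent smoothed-noise surfaces,
passing recovery tests demonstrates that the selection and validation
machinery is correct and unbiased under known truth; it does not
demonstrate robustness to the collinearity, spatial autocorrelation of
residuals, or observation biases of real satellite data (the base
fields and their PC gradients do share some correlation, which the
Spearman screen reports).

## Problem sizes used in tests

The test and acceptance runs use the study's geographic bounds at a
desk-scale 0.5° resolution (70 × 200 = 14,000 cells) with 600 presence
cells, 100 pseudo-absence sets and 100 replicates; ensemble statistics
depend on the occurrence and replicate counts, not the lattice
resolution, and the full 0.04° lattice is exercised for grid indexing.
Under those fixed-seed conditions the ensemble recovers all three true
terms with correct signs in 100/100 replicates with mean AUC ≈ 0.71,
and the label-shuffled null sits at AUC ≈ 0.50.

## Known limitations

* Pseudo-absence sampling is uniform over the surveyed area; no
  target-group weighting, distance decay or accessibility modelling.
* No spatial-autocorrelation correction in the GLMs; replicate AUCs
  treat cells as exchangeable.
* The stepwise/AIC machinery assumes main effects only; smooth terms
  (GAMs) and regularized fits are out of scope.
* Only geographic lon/lat grids are supported; no reprojection.
* The duration convention (end minus deployment) is a reporting choice;
  departure-based conventions give different numbers and are not used.
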