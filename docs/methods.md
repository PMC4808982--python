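# Methods

## The estimation problem

The package targets semi-ecological study designs: health outcomes are
observed at a fine spatial unit (a census block or district), and exposure
must be assigned to the unit's *population* over a disease latency window
of L years before the reference year j. Two facts complicate the
assignment. First, modelled annual concentration fields (dispersion or
assimilation output) typically cover only a recent period, while the
window reaches further back; earlier years must be reconstructed from the
monitoring network, which is sparse but long-lived. Second, the population
of a unit is not sedentary: a fraction of today's residents lived
elsewhere earlier in the window, so the unit's own concentration history
is the wrong exposure history for them.

The method assumes the setting in which this kind of correction is
worthwhile: between-unit variability of annual means is large compared
with within-unit (temporal) variability, and the pollutant (NO₂ is the
motivating case) has strong fine-scale spatial structure.

## Station assignment

Units and stations are embedded in a common feature space: annual mean
concentrations over the years shared by all entities, standardized per
entity to zero mean and unit sample variance. Stations are annualized from
daily series first; a year counts only if at least a fraction
`min_completeness` (default 0.75, the usual monitoring-network convention)
of its days is observed. Constant profiles carry no temporal information
and are excluded with a warning.

Entities are grouped by hierarchical agglomerative clustering under
correlation distance (1 − Pearson r) with average linkage. Correlation
distance is chosen deliberately: a traffic station can track a unit's
temporal dynamics at two or three times its absolute level, and only the
shape of the trajectory matters for choosing a temporal proxy. The number
of clusters is user-set, or selected by maximum mean silhouette over
k ∈ 2…min(10, n−1). Within its cluster each unit takes the nearest station
(planar Euclidean distance) as index monitor.

Determinism: entities are processed in lexicographic id order, distance
computation forces a contiguous array so BLAS summation order cannot
depend on input layout, and exact ties (equal distances, equal merge
heights) resolve lexicographically. Shuffling input rows therefore never
changes labels, assignments or the dendrogram.

A note on recoverability: clusters that differ only in the *slope* of a
log-linear trend have nearly identical standardized profiles (an
exponential over a decade is almost linear), so they are separable only
when slope contrast is large relative to the annualized noise. This is a
property of the problem, not of the implementation; the cluster-recovery
tests use configurations with strong contrast (e.g. factors 0.85 / 0.97 /
1.12 per year), and the generator's realistic defaults deliberately sit in
the harder regime.

## Retrospective reconstruction

Each series (station, annualized; unit, annual field) gets an ordinary
least-squares log-linear trend, log E = α + β·year. The back-cast itself
uses a per-unit calibration on the index monitor over the overlap years:

    log E_N(y) = a_N + b_N · log S_m(y),      Ê_N(y) = exp(a_N + b_N log S_m(y))

with S_m(y) the monitor's observed annual mean when available and its
trend extrapolation otherwise. The published description of this step —
weighting the unit's annual average by the coefficient from the monitor's
time-series analysis — is not given as an equation; the log-log regression
is this package's formalization of it. It reduces to plain ratio weighting
when b = 1, never produces negative concentrations, and is exactly
invertible when the data are generated from the same model class, which
gives the parameter-recovery tests a sharp target (mean absolute relative
error at machine precision on noise-free bundles). A pure ratio model
(b fixed at 1) is the automatic fallback when the monitor has zero
variance over the overlap.

Guard rails: fits require at least 3 years; back-casts are refused beyond
`max_horizon` (default 10) years before the monitor's first observed year;
per-cell uncertainty is the calibration residual sd on the log scale.

Hold-out validation refits trends and calibrations with a block of
observed years withheld — including the station observations of those
years, so the withheld block is reconstructed purely by extrapolation —
and reports per-unit and aggregate bias, mean absolute relative error
(MARE) and RMSE against the withheld unit values.

## Mobility weighting

The mobility matrix rows are indexed by destination (current residence),
columns by origin one census period of `period_years` earlier; rows sum to
one. Residence is treated as a Markov chain backwards in time: the
distribution of residence L years ago is the destination←origin matrix
applied `L // period_years` times to the point mass at N, residence held
fixed within a period. No annual root of the period matrix is attempted
(roots of stochastic matrices need not be stochastic). The outside-area
state is absorbing: the census informs only where current residents came
from, so return migration cannot be represented — a documented limitation
that overstates time spent outside for long windows.

Single-year weighted exposure is the expectation of the concentration
field at year j−L under that distribution; the outside state uses the
outside-area annual series. Three policies cover the outside mass:
`require_series` (default — refuse silently dropping it),
`renormalize_interior` (consider intra-area movements only, the choice
made in the bundled Paris illustration), and `impute_area_mean`.

Cumulative exposure averages the weighted terms over L = 0…Lmax. The
printed form of the estimator divides the (Lmax+1)-term sum by Lmax; the
default here divides by the number of terms, because the literal divisor
breaks the basic sanity property that a spatially and temporally constant
field c must yield exactly c. The literal convention remains available as
`denominator="paper_literal"` for fidelity. The same divisor is applied to
the without-mobility average so the two columns stay commensurable, and
the reported relative difference is exactly `without − with`. The degree
of mobility is 100·(1−P_NN) of the period matrix.

## Synthetic data

`simulate_area` emulates the assumed data regime, with defaults chosen
once as a realistic district-level configuration: 20 units and 9 stations
(7 trend clusters), annual means modelled 2002–2012 with a hidden
1992–2001 pre-period, cluster base levels spanning 40–90 µg/m³, per-year
trend factors around a slow decline (≈ −1 %/year), unit offsets with
log-sd 0.12, a winter-peaking seasonal cycle of ±25 %, lognormal daily
noise with log-sd 0.2, and a 5-year mobility matrix with mean moving
fraction 15.5 %, half of it from outside the area at a level 20 % below
the city's geometric mean.

The generative model is multiplicative throughout: unit value =
cluster level × unit offset; station daily value = cluster level ×
seasonal factor × mean-one lognormal noise. This keeps every value
positive and places the truth inside the calibration model class, so the
reconstruction stage is exactly recoverable in the noise-free limit.
Off-diagonal mobility mass decays with inverse distance between unit
centroids. One `numpy` generator seeded from the spec drives everything;
a fixed seed reproduces the written bundle byte for byte.

What the generator does *not* emulate — and hence what passing tests do
not demonstrate about real data: non-log-linear trends (breakpoints,
plateaus), station relocations and gaps, correlated daily noise across
stations, age- or cohort-structured mobility, and return migration. The
generator defines favourable identifiability conditions; field deployments
should lean on the hold-out validation to measure the actual error.

## Numerical choices

- Concentrations are µg/m³ everywhere; coordinates are planar meters; no
  CRS handling (the only spatial operation is a distance comparison).
- Missing data are explicit NaN cells, never zeros; reading rejects
  non-positive concentrations and mobility rows off one by more than 1e-6,
  and renormalizes rows within text-rounding distance of one (leaving
  float-exact rows untouched so round-trips are bitwise lossless; files
  are written at full float precision and read with round-trip parsing).
- Year ranges of annual fields are contiguous by construction.
- Ties anywhere (merge heights, station distances) break on lexicographic
  ids; the tie-break is logged where it fires.
- Hypothesis-based property tests run derandomized; all other randomness
  is explicit `default_rng` seeds.

Problem sizes in the test suite and acceptance script are kept small by
choice — areas of 6–12 units with 3–5 stations, 50 seeds for recovery
sweeps, 20 paired seeds for the noise-monotonicity check — because every
property asserted is size-independent and exact recovery does not sharpen
with scale.

## Known limitations

- The calibration transfers the monitor's temporal shape to the unit;
  units whose trend diverges from every monitor in their cluster (the
  motivating system shows such cases) are reconstructed with the cluster's
  shape and the divergence lands in the residual sd, not the point
  estimate.
- Arrondissement-level mobility applied to census-block exposure mixes
  spatial supports; the package computes at whatever unit the matrix is
  supplied for and leaves disaggregation to the user.
- The outside area is a single aggregate state with one exposure series.
- The bundled Paris table carries two-decimal printed rounding; its
  difference column deviates from the exact subtraction by up to 0.01.
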