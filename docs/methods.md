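# Methods

This note documents the models and procedures implemented in `landseed`,
the assumptions behind them, the parameters that matter, and the design
choices made where the method family leaves the design open.

## Data model and conventions

The landscape is a single-band categorical raster of five classes —
Developed (d), Forest (f), Agriculture (a), Water (w), Other (o) — plus a
Background code for cells outside the study area. Coordinates are 0-based
`(row, col)` with row 0 at the top; every module shares this convention.
Counties partition the non-background cells; each county belongs to a
*grouping* (counties sharing one transition model) and a *region* (a
reporting aggregate).

Transitions are restricted to an allowed table: Developed and Water never
donate, nothing converts into Water, and Forest/Agriculture/Other may
move among themselves and into Developed (14 allowed pairs including the
five self-transitions). Quotas are counted in **cells**; a helper converts
hectares to cells via `cell_size²` with round-half-up (0.81 ha per 90 m
cell). Self-transition quota rows are accepted in inputs but ignored —
staying put consumes no allocation.

Raster I/O uses plain-text ESRI ASCII grids (integer codes, explicit
nodata); georeferencing beyond origin/cell-size pass-through is out of
scope. Quota tables are CSV (`county,donor,target,cells`); fitted
patch-size models are JSON.

## Transition-probability surfaces

One classifier per county grouping is trained on cells sampled from a
reference time-1/time-2 pair: for every *gross* transition type observed
in the grouping (f→d is distinct from a→d; self-transitions of the donor
classes are types too), up to `per_label` cells (default 500) are drawn
without replacement. Predictors are the cell's elevation, focal maximum
slope and a topographic-wetness stand-in at 3/9/27-cell scales, distance
to water, protection status, focal percent of each class at 3/9/27, and
the time-1 class itself. Donors are Forest/Agriculture/Other only:
Developed and Water are assumed immobile.

The classifier is an established bagged-tree ensemble (scikit-learn's
`RandomForestClassifier`, 300 trees by default, `sqrt` features per
split, out-of-bag scoring) behind a thin adapter (fit /
predict-probabilities / OOB error), so the implementation can be swapped;
tree internals are deliberately not reimplemented here. Per-cell label
probabilities are masked so that `p_il1l2 = 0` wherever the cell's class
is not `l1` and disallowed pairs are zero; the generalized surface
`p̂_il = Σ_l1 p_il1l` then equals the cell's own-class probability of
ending in `l`. Masking is idempotent and the per-cell probabilities sum
to at most 1 (within 1e-9).

Focal percents use only in-study-area cells in the denominator (partial
windows at edges, no zero padding), computed exactly with an integral
image. Water cells stay in the denominator by default — water is real
landscape — with a flag to drop them. County groupings come from k-means
(10 restarts, standardized features, fixed seed) over per-county land-use
fractions, mean elevation/slope, population, income and centroid
coordinates.

## Patch-size models

Observed change patches are connected components (8-connectivity, so
diagonal neighbours join — matching the square annular windows the
allocator grows; configurable to 4) of cells sharing one (donor, target)
pair, clipped per county. Patch sizes are modelled per (county,
transition) by a negative binomial fitted on `size − 1`, so size 1 keeps
positive mass; the MLE profiles the likelihood over the dispersion `r`
(the success probability is `p = r/(r + mean)` at the optimum), started
from the method-of-moments value. Underdispersed samples, for which the
NB likelihood has no interior maximum, get a Poisson fit on `size − 1`;
all-equal samples collapse to a point mass; an empty table yields the
fallback model whose draws are always 1. A single pseudo-observation of
size 1 is appended to every table before fitting (flag-controlled),
which slightly shrinks fitted means but guarantees every observed
transition has a sampleable model. Draws are made odd by adding 1 to
even values so the patch window has a center cell.

## The seeding allocator

Per county and target class `l` (default order Developed, Forest,
Agriculture, Other — Developed first because it is terminal and
competition for donor cells matters; configurable):

1. sample `n` cells without replacement from the eligible frame and seed
   at the sampled cell with maximal `p̂_il`, breaking ties uniformly;
2. draw an odd patch size `k` from the (seed class, `l`) model, missing
   models fall back to `k = 1`;
3. build the window of in-county cells within Chebyshev distance
   `r = (k−1)/2`;
4. score candidates by `p′ = p̂ + (1 − d/r)(1 − σ)` with `σ` the
   *population* standard deviation of the candidate probabilities
   (`σ = 0` for a single candidate; `r = 0` leaves scores untouched);
   scores rank only — they may exceed 1 and are never renormalized, so
   adding a constant to all probabilities cannot change the converted
   set;
5. convert up to `k` candidates in descending score order — ties by
   ascending distance then row-major index, keeping patches compact and
   the procedure deterministic — skipping candidates whose own donor
   quota into `l` is spent rather than truncating the patch, which
   maximizes fulfillment without overshooting any `q_ml`.

**Eligible frame.** Eligible cells have `p̂_il > 0`, a current class that
is a donor other than `l`, are unconverted this step, *and belong to a
donor class that still owes quota into `l`*. The last condition is this
package's choice: without it, once one donor's quota is spent, spatially
smooth surfaces let that donor dominate the sample argmax indefinitely,
the allocator stalls on seeds that cannot convert, and satisfiable
quotas end in spurious shortfall. A spent-donor seed would also index
the patch-size model of a transition that owes nothing. With the
condition, every seed can convert at least itself, so allocation
terminates with zero shortfall whenever supply suffices. If fewer than
`n` cells are eligible, all are sampled (the effective `n` shrinks).

A target class is abandoned — remaining quota booked as shortfall — when
no eligible seed exists or `max_failed_seeds` (default 25) consecutive
seeds convert nothing (a safety net; with the quota-aware frame it fires
only in pathological configurations). The ledger identity
`converted + remaining = initial` holds throughout, and
`converted + shortfall = initial` at termination.

Counties are independent: windows are clipped to the county, and each
county uses an RNG substream seeded by `(master seed, county id)`, so
processing order cannot affect any county's result and reruns are
bit-identical.

## Fragmentation metrics and coverage

Percent forest in 3×3, 9×9 and 27×27 windows is classified into Rare
[0, 10), Patchy [10, 40), Transitional [40, 60), Dominant [60, 90) and
Interior [90, 100] — half-open bands so the continuum is partitioned
without gaps while integer percents keep their conventional band labels.
Tallies are *focal-class*: only forest cells are counted (a developed
cell surrounded by forest is ignored; a forest cell surrounded by
development is not), aggregated per region and reported in cells,
hectares, and optionally acres. Ensemble coverage per (window, region,
class) is binary — observed area inside the realized min–max range — with
the minimum absolute deviation as a percent of observed when missed.

## Trajectories

Multi-step projections chain allocations: each step recomputes the
land-use-derived predictor layers (focal percents, class layer) from the
current grid and re-predicts surfaces with the *fixed* grouping models —
geophysical and legal layers stay static, and county groupings are not
reassigned over time. A flag freezes the surfaces at the base state
instead. Each realization draws its seeding sample size uniformly from a
configured range (default 20–200). All draws come from substreams keyed
by (master seed, realization, step), so realizations are independent and
a run split across step ranges reproduces the contiguous run. Summaries
report, per (window, region, class, step), the median and Q1/Q3 (linear
interpolation between order statistics) of percent area change relative
to the base; a zero base with positive later area is flagged undefined
rather than reported as a number. Developed area is non-decreasing along
every realization because Developed never donates.

## Synthetic data

The fixture generator emulates the statistical character of reference
land-use data, not any real geography:

* **Landscapes** grow by seeded region growing with exact class counts
  (largest-remainder apportionment). Each assignment grows an existing
  same-class region with probability `clumpiness`, else lands on a
  uniformly random unassigned cell — `clumpiness = 0` is exactly a random
  permutation of the class multiset (spatially independent), values near
  1 give large contiguous patches. Default mixture: 40% forest, 30%
  agriculture, 17% other, 8% developed, 5% water.
* **Predictors** are synthesized coherently: smooth Gaussian-filtered
  elevation, slope as its gradient magnitude, a smooth wetness-index
  stand-in (not derived from flow accumulation), Euclidean distance to
  generated water, a smooth-threshold protection mask, and focal
  percents *computed* (not simulated) from the generated grid.
* **Reference pairs** plant connected change patches of requested sizes,
  grown over donor cells and separated by at least one cell so the
  extracted components reproduce the planted sizes exactly; the achieved
  sizes are returned as a truth table (growth can stall below target
  when donor supply runs out locally). Optional placement bias starts
  patches preferentially where the target class is already locally
  abundant, giving the transition models a learnable pattern signal.
* **Quotas** take a fraction of each donor's supply per transition,
  scaled down if a donor would be asked for more than 80% of its supply,
  guaranteeing feasibility.

What passing tests on these fixtures do *not* show: real landscapes have
legends, class imbalances, georeferencing and spatial autocorrelation
structure the generator only caricatures, and real transition drivers
are noisier than the planted signals; results here validate the
machinery and its invariants, not predictive skill on real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: landscapes
of 100×100 to 200×200 cells with four counties, ensembles of 5–15
realizations, classifiers of 80–300 trees. These sizes were chosen so
the full pipeline exercises every code path at statistically meaningful
sample sizes. Other numerical choices: probabilities are float64
throughout; the NB dispersion search is bounded in `[1e-4, 1e7]` on a
log scale; k-means uses 10 restarts; chi-square uniformity checks use
p > 0.001; stochastic assertions use generous margins and fixed seeds.

## Known limitations

* Quota accounting for mixed-donor patches (skip-when-spent) is one of
  several defensible readings of the method family; it never overshoots
  any per-donor quota but can under-use a window.
* The pseudo-observation biases small patch-size means downward,
  noticeably for tables of few large patches.
* No cross-county patch growth, no sub-cell allocation, no reprojection
  or CRS handling, no landscape-scale (non-focal-class) fragmentation
  metrics.
* Trajectories hold groupings and fitted models fixed; transition-model
  drift over decades is not modelled.
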