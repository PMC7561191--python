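# landseed

Stochastic seeding demand-allocation of land-use change: downscale
county-level land-use transition quotas onto fine-grain categorical
rasters, producing not one map but an *ensemble* of equally plausible
realizations for distributional analysis of landscape pattern.

## The problem and who this is for

Econometric land-use change models project *how much* land converts from
one use to another (forest to developed, agriculture to forest, …) per
county and decade, but many ecological analyses — forest fragmentation,
water yield, biodiversity — need *where* at a 30–90 m grain. Demand-
allocation algorithms bridge the gap: given a time-1 raster of classes
(Developed, Forest, Agriculture, Water, Other), a per-county quota
`q_ml` of cells to convert from donor class `m` to target class `l`, and
a modeled probability surface, they pick the cells that convert. This
package is for landscape ecologists and assessment modelers who need a
tunable, reproducible allocator plus the companion pieces: transition-
probability modelling, patch-size modelling, multi-scale fragmentation
metrics, and ensemble/trajectory summaries.

## The algorithm

For each county and target class `l`, repeat until the quota is met:

1. **Seed.** Sample `n` cells without replacement from the eligible cells
   (positive generalized transition probability `p̂_il`, current class a
   donor that still owes quota) and take the sampled cell with maximal
   `p̂_il`; ties break uniformly at random. `n` is the tuning parameter:
   `n = 1` is random allocation, `n =` all cells is contagious
   allocation.
2. **Patch size.** Draw `k` from the negative-binomial patch-size model
   fitted to reference patches of (seed class `m′` → `l`); even draws are
   bumped to odd.
3. **Window.** Form the `k × k` window of in-county cells within annular
   (Chebyshev) distance `r = (k − 1)/2` of the seed.
4. **Score.** Each candidate cell (class not `l` or Developed, `p̂ > 0`)
   gets `p′ = p̂ + (1 − d/r)(1 − σ)`, where `d` is its distance to the
   seed and `σ` the standard deviation of candidate probabilities —
   proximity wins on flat surfaces, the probabilities win on structured
   ones.
5. **Convert.** Convert up to `k` candidates in descending score order,
   skipping candidates whose own donor quota is spent; converted cells'
   probabilities are zeroed (no cell converts twice) and quotas
   decremented.

Developed and Water never convert to anything else. Counties are
processed independently with per-county RNG substreams, so results are
bit-reproducible and independent of processing order.

Probability surfaces come from per-county-grouping random-forest
classifiers over gross transition types (trained on up to 500 sampled
cells per type, with topographic, hydrologic, legal and focal land-use
pattern predictors); evaluation classifies each forest cell's percent
forest in 3×3/9×9/27×27 windows into Interior (90–100%), Dominant
(60–89%), Transitional (40–59%), Patchy (10–39%) or Rare (0–9%) bands
and asks whether observed per-class areas fall inside the ensemble's
min–max range.

## Worked example

`examples/` holds one short script per capability. For instance,
allocating the same quotas at both ends of the seeding continuum
(`python examples/03_allocate_realizations.py`):

```
n=   1: converted 1308 cells (shortfall 0), interior forest 3 ha
n= 256: converted 1308 cells (shortfall 0), interior forest 26 ha
```

Both runs satisfy every county quota exactly (1308 cells converted, no
shortfall), but random seeding (`n = 1`) scatters the conversions and
destroys nearly all interior forest, while near-contagious seeding
(`n = 256`) clusters them, leaving 26 ha of interior forest intact —
the spread between these extremes is precisely the within-scenario
variability an ensemble of realizations quantifies. The other examples
build landscapes (`01`), fit the transition classifier and patch-size
models from a reference pair (`02`), and project a three-step trajectory
ensemble with interquartile bands (`04`).

A thin CLI wraps the same workflows:

```bash
landseed simulate-data --shape 100 100 --counties 2 2 --out data/
landseed allocate --t1 data/landuse_t1.asc --counties data/counties.asc \
    --quotas data/quotas.csv --n 64 --seed 1 --out t2.asc --report report.csv
```

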