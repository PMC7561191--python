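"""Hybrid seeding demand-allocation of county transition quotas.

Each county owes a quota of cells converting from donor class ``m`` to
target class ``l``.  For a target class, the allocator repeatedly:

1. draws ``n`` eligible cells without replacement and takes the one with
   the highest generalized transition probability ``p̂_il`` as the *seed*
   (ties among the draws broken uniformly at random) — ``n`` tunes the
   continuum from random allocation (``n = 1``) to contagious allocation
   (``n`` = all eligible cells);
2. samples an odd patch size ``k`` from the patch-size model fitted for
   (seed's class ``m′``, target ``l``) and forms the square window of
   in-county cells within Chebyshev ("annular") distance ``r = (k−1)/2``
   of the seed;
3. scores every candidate cell in the window (current class neither the
   target nor Developed, positive probability of converting) as
   ``p + (1 − d/r)(1 − σ)`` where ``d`` is the cell's distance to the seed
   and ``σ`` the standard deviation of candidate probabilities — nearby
   cells are favored unless the local surface is strongly structured;
4. converts up to ``k`` candidates in descending score order, skipping
   candidates whose own donor quota is spent, zeroing each converted
   cell's probabilities and decrementing the matching quota.

A target class is abandoned (remaining quota booked as shortfall) when no
eligible seed remains or a run of seeds converts nothing.  Counties are
processed independently with per-county RNG substreams, so processing
order never changes the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .grid import (
    ClassCode,
    CountyPartition,
    DONOR_CLASSES,
    LandUseGrid,
    QuotaLedger,
    TransitionKey,
)
from .patches import PatchSizeModel, sample_patch_size
from .probability import TransitionProbabilityStack

__all__ = [
    "SeedingConfig",
    "SeedSelection",
    "PatchWindow",
    "AllocationReport",
    "NoEligibleSeed",
    "annular_distance",
    "select_seed",
    "build_patch_window",
    "distance_modify",
    "convert_patch",
    "allocate_county",
    "allocate_all",
]

DEFAULT_CLASS_ORDER = (
    ClassCode.DEVELOPED,
    ClassCode.FOREST,
    ClassCode.AGRICULTURE,
    ClassCode.OTHER,
)


class NoEligibleSeed(Exception):
    """No cell can seed a conversion to the requested target class."""


@dataclass
class SeedingConfig:
    """Tuning knobs for the allocator.

    ``sample_size`` is the seeding sample size ``n``; ``max_failed_seeds``
    consecutive zero-conversion seeds abandon the current target class.
    """

    sample_size: int = 64
    target_class_order: tuple[ClassCode, ...] = DEFAULT_CLASS_ORDER
    rng_seed: int = 0
    max_failed_seeds: int = 25

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise ValueError("seeding sample size n must be >= 1")
        order = list(self.target_class_order)
        if len(set(order)) != len(order):
            raise ValueError("target_class_order must not repeat classes")


@dataclass(frozen=True)
class SeedSelection:
    cell: tuple[int, int]
    donor_class: ClassCode
    generalized_probability: float


@dataclass
class PatchWindow:
    """Square annular window around a seed, clipped to county and study area."""

    seed: tuple[int, int]
    radius: int
    rows: np.ndarray        # member cell coordinates
    cols: np.ndarray
    distances: np.ndarray   # Chebyshev distance to the seed, per member
    candidate: np.ndarray   # boolean flag per member
    probabilities: np.ndarray  # generalized probability to the target, per member

    @property
    def n_candidates(self) -> int:
        return int(self.candidate.sum())


def annular_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Chebyshev distance max(|Δrow|, |Δcol|) between two cells."""
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


def select_seed(
    generalized: np.ndarray,
    eligible: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> tuple[tuple[int, int], float]:
    """Sample ``n`` eligible cells without replacement; return the best.

    The seed is the sampled cell with the maximum generalized probability;
    ties among the sampled cells are broken by a uniform random choice.
    When fewer than ``n`` cells are eligible, all of them are sampled (the
    effective ``n`` shrinks to the frame).
    """
    rr, cc = np.nonzero(eligible)
    if rr.size == 0:
        raise NoEligibleSeed("no eligible seed cells")
    take = min(n, rr.size)
    if take == rr.size:
        pick = np.arange(rr.size)
    else:
        pick = rng.choice(rr.size, size=take, replace=False)
    probs = generalized[rr[pick], cc[pick]]
    best = probs.max()
    tied = np.nonzero(probs == best)[0]
    chosen = tied[0] if tied.size == 1 else tied[rng.integers(tied.size)]
    idx = pick[chosen]
    return (int(rr[idx]), int(cc[idx])), float(best)


def build_patch_window(
    seed: tuple[int, int],
    k: int,
    county_mask: np.ndarray,
    grid: LandUseGrid,
    generalized: np.ndarray,
    target: ClassCode,
) -> PatchWindow:
    """The k×k window of in-county cells around a seed, with candidate flags.

    Candidates are cells whose current class is a donor class other than the
    target (Developed and Water never donate) and whose generalized
    probability of converting to the target is positive.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError(f"patch size k must be odd and >= 1, got {k}")
    r = (k - 1) // 2
    nrows, ncols = grid.shape
    r0, r1 = max(0, seed[0] - r), min(nrows, seed[0] + r + 1)
    c0, c1 = max(0, seed[1] - r), min(ncols, seed[1] + r + 1)
    sub = county_mask[r0:r1, c0:c1] & ~grid.background_mask[r0:r1, c0:c1]
    rr, cc = np.nonzero(sub)
    rr = rr + r0
    cc = cc + c0
    dist = np.maximum(np.abs(rr - seed[0]), np.abs(cc - seed[1]))
    cls = grid.values[rr, cc]
    probs = generalized[rr, cc]
    candidate = (
        np.isin(cls, [c for c in DONOR_CLASSES if c != target])
        & (probs > 0.0)
    )
    return PatchWindow(seed, r, rr, cc, dist, candidate, probs)


def distance_modify(window: PatchWindow) -> np.ndarray:
    """Distance-modified conversion scores for the window's candidates.

    ``score = p + (1 − d/r)(1 − σ)`` with ``σ`` the population standard
    deviation of the candidate probabilities.  With ``r = 0`` (single-cell
    window) scores equal the raw probabilities.  Scores are rank-only: they
    may exceed 1 and are never renormalized.
    """
    p = window.probabilities[window.candidate]
    if p.size == 0:
        return p
    if window.radius == 0:
        return p.copy()
    sigma = float(np.std(p))  # population SD; 0 for a single candidate
    d = window.distances[window.candidate]
    return p + (1.0 - d / window.radius) * (1.0 - sigma)


def convert_patch(
    window: PatchWindow,
    scores: np.ndarray,
    k: int,
    ledger: QuotaLedger,
    target: ClassCode,
    grid: LandUseGrid,
    stack: TransitionProbabilityStack,
) -> list[tuple[int, int]]:
    """Convert up to ``k`` candidates in descending score order.

    Ties are broken by ascending distance to the seed, then row-major cell
    index, keeping the procedure deterministic and patches compact.  A
    candidate is skipped (not counted) when the quota for its own donor
    class into the target is spent; conversion stops after ``k`` cells or
    when candidates run out.  Each converted cell's class becomes the
    target, its probabilities are zeroed and its donor quota decremented.
    """
    idx = np.nonzero(window.candidate)[0]
    if idx.size == 0:
        return []
    order = np.lexsort((
        window.rows[idx] * grid.shape[1] + window.cols[idx],
        window.distances[idx],
        -scores,
    ))
    converted: list[tuple[int, int]] = []
    for j in order:
        if len(converted) >= k:
            break
        i = idx[j]
        row, col = int(window.rows[i]), int(window.cols[i])
        donor = ClassCode(int(grid.values[row, col]))
        key = TransitionKey(donor, target)
        if ledger.remaining.get(key, 0) <= 0:
            continue
        grid.values[row, col] = target
        stack.zero_cell(row, col)
        ledger.decrement(key)
        converted.append((row, col))
    return converted


@dataclass
class AllocationReport:
    """Per-county outcome of one allocation pass."""

    county: int
    n: int
    rng_seed: int
    initial: dict[TransitionKey, int] = field(default_factory=dict)
    converted: dict[TransitionKey, int] = field(default_factory=dict)
    shortfall: dict[TransitionKey, int] = field(default_factory=dict)
    seeds_drawn: int = 0
    patches_placed: int = 0


def _eligible_mask(
    grid: LandUseGrid,
    county_mask: np.ndarray,
    generalized: np.ndarray,
    target: ClassCode,
    ledger: QuotaLedger | None = None,
) -> np.ndarray:
    """Seed sampling frame for one target class.

    Cells with a positive generalized probability of converting to the
    target whose current class is a donor class other than the target;
    given a ledger, donors whose quota into the target is spent are dropped
    from the frame — such a seed would reference the patch model of a
    transition that owes nothing, and a single-cell patch around it could
    never convert, so excluding them guarantees progress.
    """
    donors = [c for c in DONOR_CLASSES if c != target]
    if ledger is not None:
        donors = [
            d for d in donors
            if ledger.remaining.get(TransitionKey(d, target), 0) > 0
        ]
    return county_mask & (generalized > 0.0) & np.isin(grid.values, donors)


def allocate_county(
    grid: LandUseGrid,
    county_mask: np.ndarray,
    stack: TransitionProbabilityStack,
    ledger: QuotaLedger,
    patch_models: Mapping[TransitionKey, PatchSizeModel],
    config: SeedingConfig,
    rng: np.random.Generator,
) -> AllocationReport:
    """Allocate one county's quotas in place.

    ``grid`` and ``stack`` are mutated (cells outside ``county_mask`` are
    never touched).  Target classes are processed in the configured order;
    within a class, seeding repeats until the quota is met or the class is
    abandoned with a recorded shortfall.  A transition with no patch-size
    model falls back to single-cell patches (``k = 1``).
    """
    if county_mask.shape != grid.shape or stack.shape != grid.shape:
        raise ValueError("grid, county mask and probability stack misaligned")
    if not county_mask.any():
        raise ValueError(f"county {ledger.county_id}: empty mask")

    report = AllocationReport(
        county=ledger.county_id,
        n=config.sample_size,
        rng_seed=config.rng_seed,
        initial=dict(ledger.initial),
    )
    fallback = PatchSizeModel(ledger.county_id,
                              TransitionKey(ClassCode.FOREST, ClassCode.FOREST),
                              "fallback")
    targets = [t for t in config.target_class_order if ledger.remaining_to(t) > 0]
    for target in targets:
        gen = stack.generalized.get(target)
        if gen is None:
            ledger.record_shortfall(target)
            continue
        failed = 0
        while ledger.remaining_to(target) > 0:
            eligible = _eligible_mask(grid, county_mask, gen, target, ledger)
            try:
                cell, prob = select_seed(gen, eligible, config.sample_size, rng)
            except NoEligibleSeed:
                ledger.record_shortfall(target)
                break
            report.seeds_drawn += 1
            donor = ClassCode(int(grid.values[cell]))
            model = patch_models.get(TransitionKey(donor, target), fallback)
            k = sample_patch_size(model, rng)
            window = build_patch_window(cell, k, county_mask, grid, gen, target)
            scores = distance_modify(window)
            converted = convert_patch(window, scores, k, ledger, target, grid, stack)
            if converted:
                report.patches_placed += 1
                failed = 0
            else:
                failed += 1
                if failed >= config.max_failed_seeds:
                    ledger.record_shortfall(target)
                    break
    for key in ledger.initial:
        report.converted[key] = ledger.converted(key)
        report.shortfall[key] = ledger.shortfall[key]
    return report


def county_rng(master_seed: int, county_id: int) -> np.random.Generator:
    """Deterministic per-county RNG substream, independent of county order."""
    return np.random.default_rng([master_seed & 0x7FFFFFFF, county_id])


def allocate_all(
    t1: LandUseGrid,
    counties: CountyPartition,
    stack: TransitionProbabilityStack,
    ledgers: Mapping[int, QuotaLedger],
    patch_models: Mapping[tuple[int, TransitionKey], PatchSizeModel],
    config: SeedingConfig,
    county_order: Sequence[int] | None = None,
) -> tuple[LandUseGrid, dict[int, AllocationReport]]:
    """Allocate every county's quotas on a copy of the time-1 grid.

    Counties are independent: windows never cross a county line and each
    county draws from its own RNG substream derived from
    ``(config.rng_seed, county id)``, so any processing order yields a
    bit-identical result.  Ledgers are mutated in place.  Per-county errors
    are collected in the reports; processing continues past them.
    """
    counties.validate_against(t1)
    t2 = t1.copy()
    work = stack.copy()
    reports: dict[int, AllocationReport] = {}
    order = list(county_order) if county_order is not None else counties.county_ids
    for county in order:
        ledger = ledgers.get(county)
        if ledger is None:
            raise ValueError(f"county {county} has no quota ledger")
        models = {
            key: m for (c, key), m in patch_models.items() if c == county
        }
        rng = county_rng(config.rng_seed, county)
        reports[county] = allocate_county(
            t2, counties.mask(county), work, ledger, models, config, rng
        )
    return t2, reports
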