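"""Synthetic landscapes, predictors, reference pairs and quotas.

Everything the pipeline consumes can be generated here with controlled
spatial structure: categorical landscapes grown by seeded region growing
(exact class counts, tunable clumpiness), predictor stacks with smooth
geophysical fields, reference time-1/time-2 pairs with *planted* transition
patches whose true sizes are returned alongside the data, and feasible
quota tables.  Fixtures emulate the broad statistical character of national
land-use rasters — clumped classes, spatially structured predictors,
patchy change — not any real geography or legend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import (
    ALLOWED_MATRIX,
    ClassCode,
    CountyPartition,
    DONOR_CLASSES,
    LandUseGrid,
    REAL_CLASSES,
    TransitionKey,
    is_allowed,
)
from .probability import PredictorStack, TransitionProbabilityStack, compute_focal_percent

__all__ = [
    "LandscapeRecipe",
    "ChangeRecipe",
    "generate_landscape",
    "generate_reference_pair",
    "generate_quotas",
    "random_probability_stack",
    "peaked_probability_stack",
]

DEFAULT_MIXTURE = {
    ClassCode.DEVELOPED: 0.08,
    ClassCode.FOREST: 0.40,
    ClassCode.AGRICULTURE: 0.30,
    ClassCode.WATER: 0.05,
    ClassCode.OTHER: 0.17,
}

_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class LandscapeRecipe:
    """Recipe for one synthetic landscape.

    ``clumpiness`` in [0, 1] is the probability that each cell assignment
    grows an existing same-class region instead of landing on a uniformly
    random unassigned cell; 0 gives spatially independent labels, values
    near 1 give large contiguous patches.  ``county_layout`` tiles the grid
    into a (rows, cols) grid of rectangular counties.
    """

    shape: tuple[int, int] = (100, 100)
    county_layout: tuple[int, int] = (2, 2)
    mixture: dict[ClassCode, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE))
    clumpiness: float = 0.85
    n_groupings: int = 1
    n_regions: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mixture must sum to 1, got {total}")
        if not 0.0 <= self.clumpiness <= 1.0:
            raise ValueError("clumpiness must lie in [0, 1]")


def _exact_counts(mixture: Mapping[ClassCode, float], total: int) -> dict[ClassCode, int]:
    """Largest-remainder apportionment of ``total`` cells to classes."""
    raw = {c: f * total for c, f in mixture.items() if f > 0}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    leftovers = sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)
    short = total - sum(counts.values())
    for c in leftovers[:short]:
        counts[c] += 1
    return {c: n for c, n in counts.items() if n > 0}


def _grow_classes(shape: tuple[int, int], counts: dict[ClassCode, int],
                  clumpiness: float, rng: np.random.Generator) -> np.ndarray:
    """Seeded region growing honoring exact per-class cell counts."""
    rows, cols = shape
    values = np.zeros(shape, dtype=np.int16)
    unassigned = np.ones(shape, dtype=bool)
    pool = [(r, c) for r in range(rows) for c in range(cols)]
    rng.shuffle(pool)
    classes = list(counts)
    remaining = np.array([counts[c] for c in classes], dtype=float)
    frontier: dict[ClassCode, list[tuple[int, int]]] = {c: [] for c in classes}

    def pop_random_unassigned() -> tuple[int, int]:
        while True:
            cell = pool.pop()
            if unassigned[cell]:
                return cell

    total = remaining.sum()
    while total > 0:
        ci = rng.choice(len(classes), p=remaining / total)
        cls = classes[ci]
        cell = None
        if clumpiness > 0 and frontier[cls] and rng.random() < clumpiness:
            fl = frontier[cls]
            while fl:
                j = int(rng.integers(len(fl)))
                fl[j], fl[-1] = fl[-1], fl[j]
                cand = fl.pop()
                if unassigned[cand]:
                    cell = cand
                    break
        if cell is None:
            cell = pop_random_unassigned()
        values[cell] = cls
        unassigned[cell] = False
        remaining[ci] -= 1
        total -= 1
        r, c = cell
        for dr, dc in _NEIGHBORS8:
            nr, nc = r + dr, c + dc
            if 0 <= nr < rows and 0 <= nc < cols and unassigned[nr, nc]:
                frontier[cls].append((nr, nc))
    return values


def _county_labels(shape: tuple[int, int], layout: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    brows = np.minimum(np.arange(rows) * layout[0] // rows, layout[0] - 1)
    bcols = np.minimum(np.arange(cols) * layout[1] // cols, layout[1] - 1)
    return (brows[:, None] * layout[1] + bcols[None, :] + 1).astype(np.int32)


def _smooth_field(shape: tuple[int, int], sigma: float,
                  rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=sigma, mode="nearest")
    return (f - f.mean()) / (f.std() + 1e-12)


def _build_predictors(grid: LandUseGrid, rng: np.random.Generator,
                      windows: Sequence[int] = (3, 9, 27)) -> PredictorStack:
    shape = grid.shape
    elevation = 500.0 + 300.0 * _smooth_field(shape, sigma=10, rng=rng)
    gy, gx = np.gradient(elevation, grid.cell_size)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    layers: dict[str, np.ndarray] = {"elevation": elevation}
    for w in windows:
        layers[f"max_slope_{w}"] = ndimage.maximum_filter(slope, size=w,
                                                          mode="nearest")
        # stand-in for a compound topographic (wetness) index: a smooth
        # field anticorrelated with slope, not derived from flow accumulation
        layers[f"cti_{w}"] = (
            8.0 - 0.1 * ndimage.uniform_filter(slope, size=w, mode="nearest")
            + _smooth_field(shape, sigma=w, rng=rng)
        )
    water = grid.values == ClassCode.WATER
    if water.any():
        layers["dist_water"] = ndimage.distance_transform_edt(
            ~water) * grid.cell_size
    else:
        layers["dist_water"] = np.full(shape, 1e5)
    protected = _smooth_field(shape, sigma=15, rng=rng) > 1.0
    layers["protected"] = protected.astype(float)
    for cls in REAL_CLASSES:
        for w in windows:
            layers[f"pct_{cls.letter}_{w}"] = compute_focal_percent(grid, cls, w)
    layers["land_use"] = grid.values.astype(float)
    return PredictorStack(layers)


def generate_landscape(
    recipe: LandscapeRecipe,
) -> tuple[LandUseGrid, CountyPartition, PredictorStack]:
    """Generate a landscape, its county partition and a predictor stack.

    Deterministic for a fixed recipe seed.  Class counts match the mixture
    exactly (largest-remainder rounding); counties tile the grid; counties
    are assigned round-robin to groupings and regions.
    """
    rng = np.random.default_rng(recipe.seed)
    counts = _exact_counts(recipe.mixture, recipe.shape[0] * recipe.shape[1])
    values = _grow_classes(recipe.shape, counts, recipe.clumpiness, rng)
    grid = LandUseGrid(values)
    labels = _county_labels(recipe.shape, recipe.county_layout)
    n_counties = recipe.county_layout[0] * recipe.county_layout[1]
    grouping_of = {c: (c - 1) % max(1, recipe.n_groupings)
                   for c in range(1, n_counties + 1)}
    region_of = {c: (c - 1) % max(1, recipe.n_regions)
                 for c in range(1, n_counties + 1)}
    counties = CountyPartition(labels, grouping_of, region_of)
    predictors = _build_predictors(grid, rng)
    return grid, counties, predictors


@dataclass
class ChangeRecipe:
    """Patches of change to plant between the reference dates.

    ``patches`` maps ``(county, TransitionKey)`` to the list of patch sizes
    to plant.  Planted patches are separated by at least one cell so the
    connected components of the resulting change exactly reproduce the
    planted sizes (truth-file contract).
    """

    patches: dict[tuple[int, TransitionKey], list[int]]
    placement_bias: str = "none"

    def __post_init__(self) -> None:
        if self.placement_bias not in ("none", "toward-class-edges"):
            raise ValueError(f"unknown placement bias {self.placement_bias!r}")
        for (_, key), sizes in self.patches.items():
            if not is_allowed(key) or key.is_self:
                raise ValueError(f"cannot plant disallowed transition {key}")
            if any(s < 1 for s in sizes):
                raise ValueError("planted patch sizes must be >= 1")


def generate_reference_pair(
    t1: LandUseGrid,
    counties: CountyPartition,
    change: ChangeRecipe,
    rng: np.random.Generator | None = None,
) -> tuple[LandUseGrid, LandUseGrid, dict[tuple[int, TransitionKey], list[int]]]:
    """Plant connected change patches on a copy of ``t1``.

    Returns ``(t1, t2, truth)`` where ``truth`` lists the *achieved* size of
    every planted patch (growth can stall below the requested size when the
    donor supply around the start cell runs out).  ``t2`` differs from
    ``t1`` only at planted cells.
    """
    rng = np.random.default_rng(rng)
    t2_values = t1.values.copy()
    rows, cols = t1.shape
    # blocked = changed cells dilated by one, so separate patches never touch
    blocked = np.zeros(t1.shape, dtype=bool)
    truth: dict[tuple[int, TransitionKey], list[int]] = {}

    # with edge bias, patch starts are drawn with weight increasing in the
    # local percent of the target class, so change clusters where the target
    # already exists (the pattern real conversions tend to follow)
    target_pct: dict[ClassCode, np.ndarray] = {}
    if change.placement_bias == "toward-class-edges":
        for key in {k for _, k in change.patches}:
            if key.target not in target_pct:
                target_pct[key.target] = compute_focal_percent(t1, key.target, 9)

    items = sorted(change.patches.items(),
                   key=lambda kv: (kv[0][0], str(kv[0][1])))
    for (county, key), sizes in items:
        cmask = counties.mask(county)
        achieved: list[int] = []
        for target_size in sizes:
            avail = cmask & (t2_values == key.donor) & ~blocked
            rr, cc = np.nonzero(avail)
            if rr.size == 0:
                continue
            if change.placement_bias == "toward-class-edges":
                w = np.nan_to_num(target_pct[key.target][rr, cc]) + 1.0
                w = w * w
                start_i = int(rng.choice(rr.size, p=w / w.sum()))
            else:
                start_i = int(rng.integers(rr.size))
            patch = _grow_patch(
                (int(rr[start_i]), int(cc[start_i])), target_size,
                avail, rng,
            )
            for (r, c) in patch:
                t2_values[r, c] = key.target
            for (r, c) in patch:
                blocked[max(0, r - 1):r + 2, max(0, c - 1):c + 2] = True
            achieved.append(len(patch))
        if achieved:
            truth[(county, key)] = achieved
    t2 = LandUseGrid(t2_values, t1.cell_size, t1.origin)
    return t1, t2, truth


def _grow_patch(start: tuple[int, int], size: int, avail: np.ndarray,
                rng: np.random.Generator) -> list[tuple[int, int]]:
    """Random connected growth over available cells, 8-connected."""
    rows, cols = avail.shape
    patch = [start]
    members = {start}
    frontier = [start]
    while len(patch) < size and frontier:
        j = int(rng.integers(len(frontier)))
        frontier[j], frontier[-1] = frontier[-1], frontier[j]
        r, c = frontier[-1]
        grown = False
        neigh = list(_NEIGHBORS8)
        rng.shuffle(neigh)
        for dr, dc in neigh:
            nr, nc = r + dr, c + dc
            if (0 <= nr < rows and 0 <= nc < cols and avail[nr, nc]
                    and (nr, nc) not in members):
                patch.append((nr, nc))
                members.add((nr, nc))
                frontier.append((nr, nc))
                grown = True
                break
        if not grown:
            frontier.pop()
    return patch


def generate_quotas(
    t1: LandUseGrid,
    counties: CountyPartition,
    intensity: float | Mapping[TransitionKey, float] = 0.05,
    max_donor_share: float = 0.8,
    targets: Sequence[ClassCode] | None = None,
) -> pd.DataFrame:
    """Feasible per-county quota rows: ``county, donor, target, cells``.

    ``q_ml = round(intensity × donor-class cell count)`` per county; if the
    quotas drawn on one donor exceed ``max_donor_share`` of its supply they
    are scaled down proportionally, guaranteeing a feasibility margin.
    """
    keys = [k for k in _quota_keys(targets)]
    if isinstance(intensity, Mapping):
        inten = {k: float(intensity.get(k, 0.0)) for k in keys}
    else:
        inten = {k: float(intensity) for k in keys}
    if any(not (0.0 <= v < 1.0) for v in inten.values()):
        raise ValueError("intensities must lie in [0, 1)")

    rows = []
    for county in counties.county_ids:
        cmask = counties.mask(county)
        supply = {d: int(np.sum(cmask & (t1.values == d))) for d in DONOR_CLASSES}
        want = {k: int(round(inten[k] * supply[k.donor])) for k in keys}
        for donor in DONOR_CLASSES:
            donor_keys = [k for k in keys if k.donor == donor]
            asked = sum(want[k] for k in donor_keys)
            cap = int(np.floor(max_donor_share * supply[donor]))
            if asked > cap and asked > 0:
                scale = cap / asked
                for k in donor_keys:
                    want[k] = int(np.floor(want[k] * scale))
        for k in keys:
            if want[k] > 0:
                rows.append({"county": county, "donor": k.donor.letter,
                             "target": k.target.letter, "cells": want[k]})
    return pd.DataFrame(rows, columns=["county", "donor", "target", "cells"])


def _quota_keys(targets: Sequence[ClassCode] | None) -> list[TransitionKey]:
    keys = []
    for d in DONOR_CLASSES:
        for t in REAL_CLASSES:
            if d != t and ALLOWED_MATRIX[d, t]:
                if targets is None or t in targets:
                    keys.append(TransitionKey(d, t))
    return keys


def random_probability_stack(
    grid: LandUseGrid,
    rng: np.random.Generator | None = None,
    sigma: float = 6.0,
) -> TransitionProbabilityStack:
    """Smooth synthetic transition-probability surfaces for a landscape.

    Each allowed cross transition gets a spatially smooth positive field,
    scaled so the per-cell probabilities over targets sum to < 1 (the
    remainder is the implicit stay-put probability), then donor-masked.
    """
    rng = np.random.default_rng(rng)
    stack = TransitionProbabilityStack(grid.shape)
    keys = list(stack.probs)
    n_per_donor = {d: sum(1 for k in keys if k.donor == d) for d in DONOR_CLASSES}
    for key in keys:
        f = _smooth_field(grid.shape, sigma, rng)
        # logistic squashing into (0, 1), then share the unit budget
        p = 1.0 / (1.0 + np.exp(-f))
        stack.probs[key] = 0.9 * p / n_per_donor[key.donor]
    stack.mask_donors(grid)
    return stack


def peaked_probability_stack(
    grid: LandUseGrid,
    center: tuple[float, float] | None = None,
    width: float = 12.0,
    peak: float = 0.9,
    floor: float = 0.01,
) -> TransitionProbabilityStack:
    """Strongly peaked probability surfaces (a single Gaussian bump).

    Useful for exercising the contagious end of the allocation continuum:
    with large seeding sample sizes, conversions concentrate at the bump.
    """
    rows, cols = grid.shape
    if center is None:
        center = (rows / 2.0, cols / 2.0)
    rr, cc = np.mgrid[0:rows, 0:cols]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    bump = floor + (peak - floor) * np.exp(-d2 / (2.0 * width * width))
    stack = TransitionProbabilityStack(grid.shape)
    n_targets = max(len({k.target for k in stack.probs}), 1)
    for key in stack.probs:
        stack.probs[key] = bump / n_targets
    stack.mask_donors(grid)
    return stack
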