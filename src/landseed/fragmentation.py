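"""Multi-scale focal-class forest fragmentation metrics.

Each forest cell is classified by the percent forest within a centered
window (conventionally 3×3, 9×9 and 27×27 cells) into Rare, Patchy,
Transitional, Dominant or Interior.  Only forest cells are tallied — the
metric describes the neighborhood of forest, so a developed cell surrounded
by forest does not count, while a forest cell surrounded by development
does.  Realization ensembles are assessed by *coverage*: whether the
observed per-class forest area falls inside the min–max range across
realizations, and if not, the minimum deviation as a percent of observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import ClassCode, CountyPartition, LandUseGrid
from .probability import compute_focal_percent

__all__ = [
    "FragClass",
    "FRAG_BOUNDS",
    "classify_fragmentation",
    "summarize_frag_areas",
    "assess_coverage",
    "CoverageResult",
]

DEFAULT_WINDOWS = (3, 9, 27)


class FragClass(IntEnum):
    """Forest-fragmentation class by percent forest in the focal window.

    Half-open bands: Rare [0, 10), Patchy [10, 40), Transitional [40, 60),
    Dominant [60, 90), Interior [90, 100].
    """

    RARE = 0
    PATCHY = 1
    TRANSITIONAL = 2
    DOMINANT = 3
    INTERIOR = 4


#: Band lower bounds; upper bound of each band is the next entry (100 for Interior).
FRAG_BOUNDS = (0.0, 10.0, 40.0, 60.0, 90.0)


def classify_fragmentation(percent_forest: np.ndarray) -> np.ndarray:
    """Classify percent-forest values into fragmentation classes.

    Returns an integer array of :class:`FragClass` values; NaN (no-data)
    inputs map to −1.  Values must lie in [0, 100] or be NaN.
    """
    pct = np.asarray(percent_forest, dtype=float)
    valid = ~np.isnan(pct)
    if np.any((pct[valid] < 0) | (pct[valid] > 100)):
        raise ValueError("percent forest must lie in [0, 100]")
    out = np.full(pct.shape, -1, dtype=np.int8)
    # right-open bins; 100 still falls in Interior because 90 is the last bound
    out[valid] = np.digitize(pct[valid], FRAG_BOUNDS[1:], right=False)
    return out


@dataclass
class FragSummary:
    """Forest area per fragmentation class for one (window, region)."""

    window: int
    region: int
    cells: dict[FragClass, int]
    cell_area_ha: float

    def hectares(self, frag: FragClass) -> float:
        return self.cells.get(frag, 0) * self.cell_area_ha

    def acres(self, frag: FragClass) -> float:
        return self.hectares(frag) * 2.4710538146717

    def total_forest_cells(self) -> int:
        return sum(self.cells.values())


def summarize_frag_areas(
    grid: LandUseGrid,
    counties: CountyPartition,
    windows: Sequence[int] = DEFAULT_WINDOWS,
    include_water_in_denominator: bool = True,
) -> dict[tuple[int, int], FragSummary]:
    """Tally forest area by fragmentation class, per window size and region.

    Percent forest is computed at each window scale, classified, and counts
    accumulated over forest cells only, grouped by the region of each cell's
    county.  Returns ``{(window, region): FragSummary}``.

    ``include_water_in_denominator=False`` drops Water cells from the focal
    denominator (by treating them as background for the percent computation
    only).
    """
    if include_water_in_denominator:
        pct_grid = grid
    else:
        values = grid.values.copy()
        values[values == ClassCode.WATER] = ClassCode.BACKGROUND
        pct_grid = LandUseGrid(values, grid.cell_size, grid.origin)

    forest = grid.values == ClassCode.FOREST
    region_label = np.zeros(grid.shape, dtype=np.int32)
    regions = sorted({counties.region(c) for c in counties.county_ids})
    for county in counties.county_ids:
        region_label[counties.mask(county)] = counties.region(county)

    out: dict[tuple[int, int], FragSummary] = {}
    for w in windows:
        pct = compute_focal_percent(pct_grid, ClassCode.FOREST, w)
        frag = classify_fragmentation(pct)
        for region in regions:
            sel = forest & (region_label == region)
            counts = {}
            for fc in FragClass:
                counts[fc] = int(np.sum(sel & (frag == fc)))
            out[(w, region)] = FragSummary(w, region, counts,
                                           grid.cell_area_ha())
    return out


@dataclass
class CoverageResult:
    """Ensemble coverage of one observed (window, region, class) area.

    ``deviation_pct`` is 0 when the observed area lies within the min–max
    realized range, else the minimum absolute deviation as a percent of the
    observed area (infinite when observed is 0 but realizations are not).
    """

    window: int
    region: int
    frag: FragClass
    observed: float
    realized_min: float
    realized_max: float
    deviation_pct: float

    @property
    def covered(self) -> bool:
        return self.deviation_pct == 0.0


def assess_coverage(
    observed: Mapping[tuple[int, int], FragSummary],
    ensemble: Iterable[Mapping[tuple[int, int], FragSummary]],
) -> tuple[list[CoverageResult], float]:
    """Compare observed fragmentation areas against a realization ensemble.

    Returns the per-(window, region, class) coverage results and the overall
    covered-case fraction.
    """
    ensemble = list(ensemble)
    if not ensemble:
        raise ValueError("realization ensemble is empty")
    results: list[CoverageResult] = []
    for (w, region), obs in sorted(observed.items()):
        for fc in FragClass:
            obs_area = obs.hectares(fc)
            realized = np.array([
                real[(w, region)].hectares(fc) for real in ensemble
            ])
            lo, hi = realized.min(), realized.max()
            if lo <= obs_area <= hi:
                dev = 0.0
            elif obs_area == 0:
                dev = float("inf")
            else:
                dev = 100.0 * np.min(np.abs(realized - obs_area)) / obs_area
            results.append(CoverageResult(w, region, fc, obs_area,
                                          float(lo), float(hi), float(dev)))
    frac = sum(r.covered for r in results) / len(results)
    return results, frac


def coverage_frame(results: list[CoverageResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "window": r.window,
            "region": r.region,
            "class": r.frag.name.lower(),
            "observed_ha": r.observed,
            "min_ha": r.realized_min,
            "max_ha": r.realized_max,
            "deviation_pct": r.deviation_pct,
        }
        for r in results
    ])


def summary_frame(summaries: Mapping[tuple[int, int], FragSummary]) -> pd.DataFrame:
    rows = []
    for (w, region), s in sorted(summaries.items()):
        for fc in FragClass:
            rows.append({
                "window": w,
                "region": region,
                "class": fc.name.lower(),
                "cells": s.cells.get(fc, 0),
                "hectares": s.hectares(fc),
            })
    return pd.DataFrame(rows)
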