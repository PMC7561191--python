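"""Multi-step projection ensembles and trajectory summaries.

A trajectory chains allocations across decadal-style time steps: each step
re-derives the land-use-dependent predictor layers from the current grid,
re-predicts transition probability surfaces with the *fixed* per-grouping
models, and allocates that step's quotas; the output raster feeds the next
step.  An ensemble repeats this for several realizations, each with its own
seeding sample size ``n`` drawn uniformly from a configured range, yielding
distributions of fragmentation outcomes rather than a single map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allocation import SeedingConfig, allocate_all
from .fragmentation import FragClass, FragSummary, summarize_frag_areas
from .grid import ClassCode, CountyPartition, LandUseGrid, QuotaLedger, TransitionKey
from .patches import PatchSizeModel
from .probability import (
    GroupingModel,
    PredictorStack,
    TransitionProbabilityStack,
    predict_probability_stack,
)

__all__ = [
    "TrajectorySpec",
    "Realization",
    "RealizationEnsemble",
    "run_trajectory",
    "summarize_trajectories",
]


@dataclass
class TrajectorySpec:
    """One ensemble run: base grid, per-step quotas, ensemble shape.

    ``step_quotas`` holds, per time step, the per-county quota ledgers
    (these are treated as templates and copied per realization).  ``n_range``
    is the inclusive range from which each realization's seeding sample
    size is drawn.
    """

    base: LandUseGrid
    counties: CountyPartition
    step_quotas: Sequence[Mapping[int, QuotaLedger]]
    realizations: int = 20
    n_range: tuple[int, int] = (20, 200)
    master_seed: int = 0
    target_class_order: tuple[ClassCode, ...] | None = None
    max_failed_seeds: int = 25

    def __post_init__(self) -> None:
        if self.realizations < 1:
            raise ValueError("need at least one realization")
        if self.n_range[0] > self.n_range[1] or self.n_range[0] < 1:
            raise ValueError("n_range must satisfy 1 <= low <= high")
        ids = set(self.counties.county_ids)
        for step, ledgers in enumerate(self.step_quotas):
            missing = ids - set(ledgers)
            if missing:
                raise ValueError(
                    f"step {step}: counties without ledgers: {sorted(missing)}")


@dataclass
class Realization:
    index: int
    n: int
    seed: int
    grids: list[LandUseGrid]
    summaries: list[dict[tuple[int, int], FragSummary]]
    reports: list[dict] = field(default_factory=list)
    failed: bool = False
    failure: str | None = None


@dataclass
class RealizationEnsemble:
    base: LandUseGrid
    base_summaries: dict[tuple[int, int], FragSummary]
    realizations: list[Realization]

    def summaries_at_step(self, step: int) -> list[dict[tuple[int, int], FragSummary]]:
        return [r.summaries[step] for r in self.realizations if not r.failed]


def run_trajectory(
    spec: TrajectorySpec,
    models: Mapping[int, GroupingModel],
    patch_models: Mapping[tuple[int, TransitionKey], PatchSizeModel],
    predictors: PredictorStack,
    windows: Sequence[int] = (3, 9, 27),
    refresh_probabilities: bool = True,
    first_step_index: int = 0,
) -> RealizationEnsemble:
    """Run a realization ensemble over the configured time steps.

    Per realization: ``n`` is drawn once; per step, land-use-derived
    predictor layers are recomputed from the current grid, probability
    surfaces re-predicted with the fixed grouping models (or reused from
    the base when ``refresh_probabilities=False``), and the step's quotas
    allocated.  Fully deterministic for a fixed master seed: every draw
    comes from substreams keyed by (master seed, realization, step), so
    realizations are independent and a run can be split across step ranges
    without changing results.  A step failure aborts that realization with
    a record; the ensemble continues.
    """
    base_summaries = summarize_frag_areas(spec.base, spec.counties, windows)
    frozen_stack: TransitionProbabilityStack | None = None
    realizations: list[Realization] = []
    for ridx in range(spec.realizations):
        n_rng = np.random.default_rng([spec.master_seed & 0x7FFFFFFF, ridx])
        n = int(n_rng.integers(spec.n_range[0], spec.n_range[1] + 1))
        real = Realization(index=ridx, n=n, seed=spec.master_seed,
                           grids=[], summaries=[])
        grid = spec.base
        try:
            for sidx, ledger_templates in enumerate(spec.step_quotas):
                step = first_step_index + sidx
                step_seed = int(
                    np.random.default_rng(
                        [spec.master_seed & 0x7FFFFFFF, ridx, step, 0x5EED]
                    ).integers(2**31)
                )
                if refresh_probabilities or frozen_stack is None:
                    step_predictors = predictors.with_updated_land_use(
                        grid, windows)
                    stack = predict_probability_stack(
                        models, grid, step_predictors, spec.counties)
                    if not refresh_probabilities:
                        frozen_stack = stack
                else:
                    stack = frozen_stack
                ledgers = {c: l.copy() for c, l in ledger_templates.items()}
                config = SeedingConfig(
                    sample_size=n,
                    rng_seed=step_seed,
                    max_failed_seeds=spec.max_failed_seeds,
                    **({"target_class_order": spec.target_class_order}
                       if spec.target_class_order else {}),
                )
                grid, reports = allocate_all(
                    grid, spec.counties, stack, ledgers, patch_models, config)
                real.grids.append(grid)
                real.reports.append(reports)
                real.summaries.append(
                    summarize_frag_areas(grid, spec.counties, windows))
        except ValueError as exc:
            real.failed = True
            real.failure = str(exc)
        realizations.append(real)
    return RealizationEnsemble(spec.base, base_summaries, realizations)


def summarize_trajectories(
    ensemble: RealizationEnsemble,
    windows: Sequence[int] = (3, 9, 27),
) -> pd.DataFrame:
    """Distributional trajectories of fragmentation-class area change.

    For every (window, region, class, step): percent change of forest area
    relative to the base grid, per realization, then the median and first
    and third quartiles across realizations (quantiles by linear
    interpolation between order statistics).  A base area of zero with a
    nonzero later area is flagged undefined (NaN values, ``undefined``
    True) rather than reported as a number.
    """
    ok = [r for r in ensemble.realizations if not r.failed]
    if not ok:
        raise ValueError("no surviving realizations to summarize")
    n_steps = len(ok[0].summaries)
    rows = []
    for (w, region), base_summary in sorted(ensemble.base_summaries.items()):
        if w not in windows:
            continue
        for fc in FragClass:
            base_area = base_summary.hectares(fc)
            for step in range(n_steps):
                areas = np.array([
                    r.summaries[step][(w, region)].hectares(fc) for r in ok
                ])
                if base_area == 0:
                    undefined = bool(np.any(areas > 0))
                    # 0 → 0 is an unambiguous no-change; 0 → positive is not
                    med = q1 = q3 = float("nan") if undefined else 0.0
                else:
                    undefined = False
                    change = 100.0 * (areas - base_area) / base_area
                    q1, med, q3 = np.percentile(change, [25, 50, 75],
                                                method="linear")
                rows.append({
                    "window": w,
                    "region": region,
                    "class": fc.name.lower(),
                    "step": step,
                    "median_pct": med,
                    "q1_pct": q1,
                    "q3_pct": q3,
                    "undefined": undefined,
                })
    return pd.DataFrame(rows)
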