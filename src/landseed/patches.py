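"""Observed transition patches and negative-binomial patch-size models.

Comparing two reference dates yields, per county and per allowed (donor,
target) transition, a multiset of connected-patch sizes.  Patch sizes for a
transition are modelled with a negative binomial fitted on ``size − 1`` (so
size 1 keeps positive mass), with a single pseudo-observation of size 1
appended to every table so that transitions with no or degenerate reference
data still yield a usable model.  During allocation the fitted model is
sampled for the patch size ``k``; even draws are bumped to the next odd
number so the patch window has a well-defined center cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .grid import (
    ClassCode,
    CountyPartition,
    LandUseGrid,
    TransitionKey,
    allowed_cross_transitions,
)

__all__ = [
    "PatchTable",
    "PatchSizeModel",
    "extract_transition_patches",
    "fit_patch_distribution",
    "fit_patch_models",
    "sample_patch_size",
    "save_patch_models",
    "load_patch_models",
]

# 8-connectivity: diagonal neighbours join a patch, matching the square
# annular windows the allocator grows.
STRUCTURE_8 = np.ones((3, 3), dtype=bool)
STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class PatchTable:
    """Multiset of observed patch sizes for one (county, transition)."""

    county: int
    key: TransitionKey
    sizes: list[int]

    def total_cells(self) -> int:
        return sum(self.sizes)


def extract_transition_patches(
    t1: LandUseGrid,
    t2: LandUseGrid,
    counties: CountyPartition,
    connectivity: int = 8,
) -> dict[tuple[int, TransitionKey], PatchTable]:
    """Connected components of change, per county and allowed transition.

    A patch is a maximal connected set of cells sharing the same donor class
    at time 1 and the same (different) target class at time 2, clipped to a
    single county: change straddling a county line is split at the border.
    """
    if t1.shape != t2.shape or counties.labels.shape != t1.shape:
        raise ValueError("grids and county partition must share one shape")
    structure = STRUCTURE_8 if connectivity == 8 else STRUCTURE_4
    tables: dict[tuple[int, TransitionKey], PatchTable] = {}
    for county in counties.county_ids:
        cmask = counties.mask(county)
        for key in allowed_cross_transitions():
            mask = cmask & (t1.values == key.donor) & (t2.values == key.target)
            if not mask.any():
                continue
            labelled, n = ndimage.label(mask, structure=structure)
            sizes = np.bincount(labelled.ravel())[1:]
            tables[(county, key)] = PatchTable(county, key, sizes.tolist())
    return tables


@dataclass
class PatchSizeModel:
    """Patch-size distribution for one (county, transition).

    ``kind`` is one of:

    * ``"nbinom"`` — negative binomial on ``size − 1`` with dispersion
      ``r_nb`` and success probability ``p_nb``;
    * ``"poisson"`` — Poisson on ``size − 1`` (used when the sample is
      underdispersed, where the NB likelihood has no interior maximum);
    * ``"point"`` — all observed sizes equal; sampling returns that size;
    * ``"fallback"`` — no observations at all; sampling always returns 1.
    """

    county: int
    key: TransitionKey
    kind: str
    r_nb: float | None = None
    p_nb: float | None = None
    lam: float | None = None
    point: int | None = None
    fitted_on: int = 0

    @property
    def fallback(self) -> bool:
        return self.kind == "fallback"

    def mean_size(self) -> float:
        """Expected patch size (before the odd-rounding adjustment)."""
        if self.kind == "nbinom":
            return 1.0 + self.r_nb * (1.0 - self.p_nb) / self.p_nb
        if self.kind == "poisson":
            return 1.0 + self.lam
        if self.kind == "point":
            return float(self.point)
        return 1.0


def _nbinom_mle(x: np.ndarray) -> tuple[float, float]:
    """Profile MLE of the negative binomial on counts ``x`` ≥ 0.

    For fixed dispersion ``r`` the likelihood is maximized at
    ``p = r / (r + mean)``, so only ``r`` is searched (on a log grid via a
    bounded scalar minimizer), started from the method-of-moments value.
    """
    mean = x.mean()
    var = x.var()
    r0 = mean * mean / (var - mean) if var > mean else 1.0
    r0 = float(np.clip(r0, 1e-3, 1e6))

    def nll(log_r: float) -> float:
        r = np.exp(log_r)
        p = r / (r + mean)
        return -stats.nbinom.logpmf(x, r, p).sum()

    res = optimize.minimize_scalar(
        nll,
        bracket=(np.log(r0) - 1.0, np.log(r0), np.log(r0) + 1.0)
        if r0 > 2e-3 else None,
        bounds=(np.log(1e-4), np.log(1e7)),
        method="bounded",
    )
    r = float(np.exp(res.x))
    p = r / (r + mean)
    return r, float(p)


def fit_patch_distribution(
    sizes: Iterable[int],
    county: int = 0,
    key: TransitionKey | None = None,
    add_pseudo: bool = True,
) -> PatchSizeModel:
    """Fit a patch-size model to a multiset of observed sizes.

    An empty multiset yields the fallback model (patch size always 1).
    Otherwise a pseudo-observation of size 1 is appended (``add_pseudo``),
    sizes are shifted by −1 and a negative binomial is fitted by maximum
    likelihood; underdispersed samples get a Poisson fit instead, and
    all-equal samples collapse to a point mass.
    """
    if key is None:
        key = TransitionKey(ClassCode.FOREST, ClassCode.DEVELOPED)
    sizes = [int(s) for s in sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("patch sizes must be positive integers")
    if not sizes:
        return PatchSizeModel(county, key, "fallback", fitted_on=0)
    n_obs = len(sizes)
    if add_pseudo:
        sizes = sizes + [1]
    x = np.asarray(sizes, dtype=np.int64) - 1
    if np.all(x == x[0]):
        return PatchSizeModel(county, key, "point", point=int(x[0]) + 1,
                              fitted_on=n_obs)
    mean, var = x.mean(), x.var()
    if var <= mean:
        return PatchSizeModel(county, key, "poisson", lam=float(mean),
                              fitted_on=n_obs)
    r, p = _nbinom_mle(x)
    return PatchSizeModel(county, key, "nbinom", r_nb=r, p_nb=p, fitted_on=n_obs)


def fit_patch_models(
    tables: dict[tuple[int, TransitionKey], PatchTable],
    add_pseudo: bool = True,
) -> dict[tuple[int, TransitionKey], PatchSizeModel]:
    return {
        (county, key): fit_patch_distribution(
            tbl.sizes, county=county, key=key, add_pseudo=add_pseudo
        )
        for (county, key), tbl in tables.items()
    }


def sample_patch_size(model: PatchSizeModel, rng: np.random.Generator) -> int:
    """Draw an odd patch size ``k`` ≥ 1 from a fitted model.

    The raw draw (on the original size scale) is bumped to the next integer
    if even, so the resulting square window has a center cell.
    """
    if model.kind == "fallback":
        k = 1
    elif model.kind == "point":
        k = model.point
    elif model.kind == "poisson":
        k = 1 + int(rng.poisson(model.lam))
    else:
        k = 1 + int(_nbinom_draw(model.r_nb, model.p_nb, rng))
    if k % 2 == 0:
        k += 1
    return k


def _nbinom_draw(r: float, p: float, rng: np.random.Generator) -> int:
    # gamma-Poisson mixture keeps the draw tied to the caller's generator
    lam = rng.gamma(shape=r, scale=(1.0 - p) / p)
    return int(rng.poisson(lam))


def save_patch_models(models: dict[tuple[int, TransitionKey], PatchSizeModel],
                      path: str | Path) -> None:
    records = []
    for (county, key), m in models.items():
        rec = asdict(m)
        rec["key"] = str(key)
        records.append(rec)
    Path(path).write_text(json.dumps(records, indent=1))


def load_patch_models(path: str | Path) -> dict[tuple[int, TransitionKey], PatchSizeModel]:
    records = json.loads(Path(path).read_text())
    out = {}
    for rec in records:
        key = TransitionKey.parse(rec.pop("key"))
        m = PatchSizeModel(key=key, **rec)
        out[(m.county, key)] = m
    return out


def patch_tables_to_frame(
    tables: dict[tuple[int, TransitionKey], PatchTable]
) -> pd.DataFrame:
    """Long-format summary: county, donor, target, patch_size, count."""
    rows = []
    for (county, key), tbl in sorted(tables.items()):
        uniq, counts = np.unique(tbl.sizes, return_counts=True)
        for s, c in zip(uniq, counts):
            rows.append({
                "county": county,
                "donor": key.donor.letter,
                "target": key.target.letter,
                "patch_size": int(s),
                "count": int(c),
            })
    return pd.DataFrame(rows, columns=["county", "donor", "target",
                                       "patch_size", "count"])
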