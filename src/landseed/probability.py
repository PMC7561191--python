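"""Transition-probability surfaces from paired reference rasters.

Workflow: counties are clustered into *groupings* with similar land-use
character; within each grouping, cells that transitioned between the two
reference dates are sampled (up to a per-label cap) to train one classifier
per grouping whose labels are gross transition types (e.g. Forest→Developed
is distinct from Agriculture→Developed, and staying Forest is its own
label).  Applying a grouping's classifier to every cell yields the per-cell
transition-probability stack ``P = {p_il1l2}``; because ``p_il1l2 = 0``
whenever the cell's current class differs from the donor ``l1``, the stack
collapses to a *generalized* surface ``p̂_il = Σ_l1 p_il1l`` giving each
cell's probability of ending up in class ``l``.

The classifier itself is delegated to an established bagged-tree ensemble
(scikit-learn's random forest) behind a small adapter; only the sample
assembly, donor masking and probability collapse are bespoke.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler

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

__all__ = [
    "PredictorStack",
    "TrainingSample",
    "GroupingModel",
    "TransitionProbabilityStack",
    "compute_focal_percent",
    "cluster_counties",
    "assemble_training_sample",
    "fit_grouping_model",
    "predict_probability_stack",
]

NODATA = float("nan")


def compute_focal_percent(grid: LandUseGrid, cls: ClassCode, window: int) -> np.ndarray:
    """Percent of a class within a centered square window at every cell.

    The denominator counts only in-study-area (non-background) cells in the
    window, so partial windows at grid edges or next to background use the
    cells actually present rather than zero padding.  Background cells get
    NaN.

    Parameters
    ----------
    window
        Odd window edge length in cells (3, 9 and 27 are the conventional
        scales; any odd value ≥ 1 works).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive integer, got {window}")
    valid = (~grid.background_mask).astype(np.int64)
    hits = ((grid.values == cls) & ~grid.background_mask).astype(np.int64)
    r = window // 2
    n_valid = _box_sum(valid, r)
    n_hits = _box_sum(hits, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * n_hits / n_valid
    pct[n_valid == 0] = np.nan
    pct[grid.background_mask] = np.nan
    return pct


def _box_sum(arr: np.ndarray, r: int) -> np.ndarray:
    """Sum over a (2r+1)² window via an integral image; exact for ints."""
    rows, cols = arr.shape
    ii = np.zeros((rows + 1, cols + 1), dtype=np.int64)
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=ii[1:, 1:])
    r0 = np.clip(np.arange(rows) - r, 0, rows)
    r1 = np.clip(np.arange(rows) + r + 1, 0, rows)
    c0 = np.clip(np.arange(cols) - r, 0, cols)
    c1 = np.clip(np.arange(cols) + r + 1, 0, cols)
    return (
        ii[np.ix_(r1, c1)] - ii[np.ix_(r0, c1)] - ii[np.ix_(r1, c0)]
        + ii[np.ix_(r0, c0)]
    )


@dataclass
class PredictorStack:
    """Named predictor layers aligned to a land-use grid.

    Standard layers are elevation, focal maximum slope and a compound
    topographic index at 3/9/27-cell scales, distance to the nearest
    waterbody, a binary protection status, focal percent of each class at
    3/9/27, and the current land-use class itself.  Any consistent set of
    aligned layers is accepted.
    """

    layers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"predictor layers disagree on shape: {shapes}")

    @property
    def names(self) -> list[str]:
        return sorted(self.layers)

    def matrix(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Predictor matrix (cells × layers) for the given cell coordinates."""
        return np.column_stack(
            [self.layers[name][rows, cols] for name in self.names]
        )

    def with_updated_land_use(self, grid: LandUseGrid,
                              windows: Sequence[int] = (3, 9, 27)) -> "PredictorStack":
        """Recompute the land-use-derived layers from a (new) grid.

        Geophysical and legal layers are carried over unchanged; focal class
        percents and the class layer are rebuilt, which is how multi-step
        projections keep pattern predictors in sync with the evolving
        landscape.
        """
        layers = dict(self.layers)
        for cls in REAL_CLASSES:
            for w in windows:
                name = f"pct_{cls.letter}_{w}"
                if name in layers:
                    layers[name] = compute_focal_percent(grid, cls, w)
        if "land_use" in layers:
            layers["land_use"] = grid.values.astype(float)
        return PredictorStack(layers)


def cluster_counties(features: pd.DataFrame, k: int, seed: int = 0) -> dict[int, int]:
    """Group counties by k-means on standardized per-county features.

    ``features`` is indexed by county id; typical columns are land-use
    fractions, mean elevation, mean local slope, population, income and the
    county centroid coordinates.  Returns ``county id -> grouping id`` with
    groupings numbered from 0.  Deterministic for a fixed seed (10 k-means
    restarts, best inertia kept).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(features):
        raise ValueError(f"k={k} exceeds the number of counties ({len(features)})")
    X = StandardScaler().fit_transform(features.to_numpy(dtype=float))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    return {int(c): int(g) for c, g in zip(features.index, labels)}


@dataclass
class TrainingSample:
    """Labelled cells for one grouping's transition classifier."""

    grouping: int
    labels: np.ndarray          # transition label strings, e.g. "f>d"
    X: np.ndarray               # cells × predictors
    feature_names: list[str]
    cells: np.ndarray           # (n, 2) row/col of each sampled cell

    def label_counts(self) -> dict[str, int]:
        uniq, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))


def assemble_training_sample(
    t1: LandUseGrid,
    t2: LandUseGrid,
    predictors: PredictorStack,
    counties: CountyPartition,
    grouping: int,
    per_label: int = 500,
    rng: np.random.Generator | None = None,
) -> TrainingSample:
    """Sample observed gross transitions within one county grouping.

    For every allowed (donor, target) label observed in the grouping —
    including self-transitions of the donor classes — up to ``per_label``
    cells are drawn without replacement, each carrying its predictor vector.
    Donors are restricted to Forest/Agriculture/Other: Developed and Water
    are assumed immobile and contribute no training rows.
    """
    if t1.shape != t2.shape:
        raise ValueError("time-1 and time-2 grids are misaligned")
    rng = np.random.default_rng(rng)
    member_counties = [c for c in counties.county_ids
                      if counties.grouping(c) == grouping]
    if not member_counties:
        raise ValueError(f"grouping {grouping} has no counties")
    in_group = np.isin(counties.labels, member_counties)

    rows_all, cols_all, labels_all = [], [], []
    for donor in DONOR_CLASSES:
        donor_mask = in_group & (t1.values == donor)
        for target in REAL_CLASSES:
            if not ALLOWED_MATRIX[donor, target]:
                continue
            rr, cc = np.nonzero(donor_mask & (t2.values == target))
            if rr.size == 0:
                continue
            take = min(per_label, rr.size)
            pick = rng.choice(rr.size, size=take, replace=False)
            rows_all.append(rr[pick])
            cols_all.append(cc[pick])
            labels_all.append(
                np.full(take, str(TransitionKey(donor, target)), dtype=object)
            )
    if not rows_all:
        raise ValueError(f"no transitions observed in grouping {grouping}")
    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    labels = np.concatenate(labels_all)
    return TrainingSample(
        grouping=grouping,
        labels=labels,
        X=predictors.matrix(rows, cols),
        feature_names=predictors.names,
        cells=np.column_stack([rows, cols]),
    )


@dataclass
class GroupingModel:
    """Fitted transition classifier for one county grouping.

    Thin adapter over a bagged-tree ensemble: exposes the label set, an
    out-of-bag error estimate and per-label probability prediction, so the
    underlying implementation can be swapped without touching callers.
    """

    grouping: int
    classifier: RandomForestClassifier
    labels: list[str]
    oob_error: float
    feature_names: list[str] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-label probabilities, columns ordered as ``self.labels``."""
        return self.classifier.predict_proba(X)


def fit_grouping_model(
    sample: TrainingSample,
    n_trees: int = 300,
    max_features: str | int | float = "sqrt",
    seed: int = 0,
) -> GroupingModel:
    """Fit a random-forest transition classifier for one grouping.

    Out-of-bag voting provides the error estimate.  Deterministic for a
    fixed seed.  Raises on single-label samples, for which class
    probabilities are degenerate.
    """
    label_set = np.unique(sample.labels)
    if label_set.size < 2:
        raise ValueError(
            f"grouping {sample.grouping}: need >=2 transition labels, "
            f"got {label_set.tolist()}"
        )
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(sample.X, sample.labels)
    return GroupingModel(
        grouping=sample.grouping,
        classifier=clf,
        labels=[str(c) for c in clf.classes_],
        oob_error=1.0 - float(clf.oob_score_),
        feature_names=list(sample.feature_names),
    )


class TransitionProbabilityStack:
    """Per-cell transition probabilities ``P`` and generalized surface ``P̂``.

    ``probs[key]`` holds ``p_il1l2`` for one (donor, target) pair, zero
    wherever the cell's current class is not the donor.  ``generalized[l]``
    holds ``p̂_il = Σ_l1 p_il1l``, which under donor masking equals the
    probability for the cell's own class.  The allocator mutates the stack:
    converted cells have all their probabilities zeroed.
    """

    def __init__(self, shape: tuple[int, int],
                 keys: Sequence[TransitionKey] | None = None):
        self.shape = shape
        if keys is None:
            keys = [TransitionKey(d, t) for d in DONOR_CLASSES
                    for t in REAL_CLASSES if ALLOWED_MATRIX[d, t] and d != t]
        self.probs: dict[TransitionKey, np.ndarray] = {
            k: np.zeros(shape, dtype=np.float64) for k in keys
        }
        self._generalized: dict[ClassCode, np.ndarray] | None = None

    def mask_donors(self, t1: LandUseGrid) -> None:
        """Zero every layer where the cell's current class is not the donor."""
        for key, arr in self.probs.items():
            arr[t1.values != key.donor] = 0.0
        self._generalized = None

    @property
    def generalized(self) -> dict[ClassCode, np.ndarray]:
        if self._generalized is None:
            gen: dict[ClassCode, np.ndarray] = {}
            for key, arr in self.probs.items():
                gen.setdefault(key.target, np.zeros(self.shape))
                gen[key.target] += arr
            self._generalized = gen
        return self._generalized

    def zero_cell(self, row: int, col: int) -> None:
        """Remove a cell from all further conversion consideration."""
        for arr in self.probs.values():
            arr[row, col] = 0.0
        if self._generalized is not None:
            for arr in self._generalized.values():
                arr[row, col] = 0.0

    def copy(self) -> "TransitionProbabilityStack":
        dup = TransitionProbabilityStack(self.shape, list(self.probs))
        for k in self.probs:
            dup.probs[k] = self.probs[k].copy()
        return dup


def predict_probability_stack(
    models: Mapping[int, GroupingModel],
    t1: LandUseGrid,
    predictors: PredictorStack,
    counties: CountyPartition,
) -> TransitionProbabilityStack:
    """Predict the full transition-probability stack for a landscape.

    Each county's cells are scored by its grouping's classifier; label
    probabilities whose donor is not the cell's current class are zeroed,
    as are disallowed transitions.  Developed and Water cells keep all-zero
    cross-transition probabilities — they never donate.  Self-transition
    labels are dropped from the stack (staying put requires no allocation).
    """
    counties.validate_against(t1)
    stack = TransitionProbabilityStack(t1.shape)
    for county in counties.county_ids:
        grouping = counties.grouping(county)
        model = models.get(grouping)
        if model is None:
            raise ValueError(f"county {county}: no model for grouping {grouping}")
        cmask = counties.mask(county) & ~t1.background_mask
        donorable = np.isin(t1.values, list(DONOR_CLASSES))
        rr, cc = np.nonzero(cmask & donorable)
        if rr.size == 0:
            continue
        proba = model.predict_proba(predictors.matrix(rr, cc))
        t1_here = t1.values[rr, cc]
        for j, label in enumerate(model.labels):
            key = TransitionKey.parse(label)
            if key.is_self or not is_allowed(key):
                continue
            sel = t1_here == key.donor
            if not sel.any():
                continue
            stack.probs[key][rr[sel], cc[sel]] = proba[sel, j]
    return stack
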