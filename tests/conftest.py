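import numpy as np
import pytest

from landseed.grid import ClassCode, TransitionKey
from landseed.synthetic import (
    ChangeRecipe,
    LandscapeRecipe,
    generate_landscape,
    generate_reference_pair,
)

F = ClassCode.FOREST
D = ClassCode.DEVELOPED
A = ClassCode.AGRICULTURE
W = ClassCode.WATER
O = ClassCode.OTHER


@pytest.fixture(scope="session")
def small_landscape():
    """100x100 clumpy landscape, 4 counties, 2 regions, one grouping."""
    recipe = LandscapeRecipe(
        shape=(100, 100), county_layout=(2, 2), clumpiness=0.85,
        n_groupings=1, n_regions=2, seed=42,
    )
    return generate_landscape(recipe)


@pytest.fixture(scope="session")
def reference_pair(small_landscape):
    """Reference t1/t2 pair with planted change and its truth table."""
    t1, counties, predictors = small_landscape
    patches = {}
    for c in counties.county_ids:
        patches[(c, TransitionKey(F, D))] = [5, 9, 3, 7, 12]
        patches[(c, TransitionKey(A, D))] = [4, 6, 2]
        patches[(c, TransitionKey(A, F))] = [8, 3]
        patches[(c, TransitionKey(O, A))] = [5]
    rng = np.random.default_rng(7)
    t1, t2, truth = generate_reference_pair(
        t1, counties, ChangeRecipe(patches), rng)
    return t1, t2, counties, predictors, truth
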