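"""Project a 3-step realization ensemble and summarize trajectories.

Each realization chains allocations across time steps, re-deriving the
land-use pattern predictors from the evolving grid while keeping the
fitted transition models fixed, and draws its own seeding sample size.
The summary gives median and interquartile percent change of each forest
fragmentation class relative to the base landscape.
"""

import numpy as np

from landseed import (
    ClassCode,
    QuotaLedger,
    TransitionKey,
    TrajectorySpec,
    assemble_training_sample,
    fit_grouping_model,
    generate_landscape,
    generate_reference_pair,
    run_trajectory,
    summarize_trajectories,
)
from landseed.synthetic import ChangeRecipe, LandscapeRecipe

F, D, A = ClassCode.FOREST, ClassCode.DEVELOPED, ClassCode.AGRICULTURE

t1, counties, predictors = generate_landscape(
    LandscapeRecipe(shape=(100, 100), clumpiness=0.85, seed=7))
rng = np.random.default_rng(1)
change = ChangeRecipe({(c, TransitionKey(F, D)): [5, 9, 3, 7]
                       for c in counties.county_ids},
                      placement_bias="toward-class-edges")
t1, t2, _ = generate_reference_pair(t1, counties, change, rng)
sample = assemble_training_sample(t1, t2, predictors, counties,
                                  grouping=0, per_label=300, rng=rng)
model = fit_grouping_model(sample, n_trees=100, seed=0)

step_quota = {c: QuotaLedger(c, {TransitionKey(F, D): 30,
                                 TransitionKey(A, D): 15})
              for c in counties.county_ids}
spec = TrajectorySpec(
    base=t1, counties=counties,
    step_quotas=[{c: l.copy() for c, l in step_quota.items()}
                 for _ in range(3)],
    realizations=5, n_range=(20, 200), master_seed=9)
ensemble = run_trajectory(spec, {0: model}, {}, predictors, windows=(9,))

df = summarize_trajectories(ensemble, windows=(9,))
print(df[~df.undefined].to_string(index=False))
print("\nmedian_pct is the median percent change of each fragmentation")
print("class's forest area vs the base grid across 5 realizations;")
print("q1/q3 bound the interquartile range (the ensemble's spread).")
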