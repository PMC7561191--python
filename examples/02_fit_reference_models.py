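"""Fit transition and patch-size models from a reference grid pair.

Change patches are planted on the time-1 landscape (preferentially near
existing target-class cells, as real conversions tend to be), then the two
model families of the pipeline are fitted from the pair: a random-forest
transition classifier per county grouping, and a negative-binomial patch
size model per (county, transition).
"""

import numpy as np
from scipy import stats

from landseed import (
    ClassCode,
    LandscapeRecipe,
    TransitionKey,
    assemble_training_sample,
    extract_transition_patches,
    fit_grouping_model,
    fit_patch_distribution,
    generate_landscape,
    generate_reference_pair,
)
from landseed.synthetic import ChangeRecipe

F, D, A = ClassCode.FOREST, ClassCode.DEVELOPED, ClassCode.AGRICULTURE

t1, counties, predictors = generate_landscape(
    LandscapeRecipe(shape=(100, 100), clumpiness=0.85, seed=7))

# plant forest->developed patches whose sizes follow a shifted negative
# binomial with mean 4 cells
rng = np.random.default_rng(1)
sizes = stats.nbinom.rvs(2.0, 0.4, size=120, random_state=rng) + 1
chunks = np.array_split(sizes, len(counties.county_ids))
change = ChangeRecipe(
    {(c, TransitionKey(F, D)): chunk.tolist()
     for c, chunk in zip(counties.county_ids, chunks)},
    placement_bias="toward-class-edges")
t1, t2, truth = generate_reference_pair(t1, counties, change, rng)

sample = assemble_training_sample(
    t1, t2, predictors, counties, grouping=0, per_label=500, rng=rng)
model = fit_grouping_model(sample, n_trees=150, seed=0)
print(f"transition labels sampled: {sample.label_counts()}")
print(f"out-of-bag error: {100 * model.oob_error:.1f}%")
print("(the error a fresh cell's gross transition type would be"
      " misclassified with)")

tables = extract_transition_patches(t1, t2, counties)
pooled = fit_patch_distribution(
    [s for tbl in tables.values() for s in tbl.sizes])
print(f"\npatches extracted: {sum(len(t.sizes) for t in tables.values())}")
print(f"fitted patch-size model: {pooled.kind}, mean "
      f"{pooled.mean_size():.2f} cells (generator mean 4.00)")
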