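"""Generate a synthetic landscape with counties, predictors and quotas.

The landscape is grown by seeded region growing: class fractions are hit
exactly, and the clumpiness knob controls how contiguous the classes are.
Quotas ask each county to convert a small fraction of every donor class.
"""

from landseed import LandscapeRecipe, generate_landscape
from landseed.synthetic import generate_quotas

recipe = LandscapeRecipe(
    shape=(100, 100), county_layout=(2, 2), clumpiness=0.85, seed=7)
grid, counties, predictors = generate_landscape(recipe)

print("class counts (cells):")
for cls, count in grid.class_counts().items():
    print(f"  {cls.name.lower():12s} {count:6d}")

quotas = generate_quotas(grid, counties, intensity=0.05)
print(f"\nquota table: {len(quotas)} rows, "
      f"{quotas.cells.sum()} cells of change requested")
print(quotas.head(6).to_string(index=False))
print("\nEach row asks one county to convert `cells` cells from the donor")
print("class to the target class; intensity 0.05 means 5% of each donor's")
print("supply per transition, capped to stay feasible.")
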