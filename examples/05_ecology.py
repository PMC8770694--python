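"""Environmental covariates from gridded occurrences, and why they force ols.

Habitat faunal lists are built per habitat class from well-sampled
one-degree cells, optionally keeping only the most commonly occurring
species; NPP (net primary productivity) is binned into equal-count
categories. Because one species can occupy several habitats or NPP bins,
the joined table duplicates species — fits on it must be ordinary least
squares, and the table itself refuses pgls.
"""

import pandas as pd
import craniomorph as cm
from craniomorph.ecology import assert_pgls_safe

configs, table, truth = cm.simulate_landmark_dataset(cm.SimulationSpec(seed=5))
species_pool = table["species"].tolist()

grid = cm.simulate_occurrence_grid(600, species_pool, mean_richness=8.0, seed=5)
filtered = cm.filter_cells(grid)
print(f"{filtered['cell_id'].nunique()} cells retained in "
      f"{filtered['habitat'].nunique()} habitat classes")

top20 = cm.habitat_faunal_lists(filtered, top_fraction=0.2)
for habitat, spp in sorted(top20.items()):
    print(f"  {habitat}: top-20% faunal list has {len(spp)} species")

bins, edges = cm.npp_bins(filtered)
print("NPP bin edges:", ", ".join(f"{e:.0f}" for e in edges))

joined = cm.join_covariates(table, top20, bins=(bins, edges), occurrence=filtered)
print(f"joined table: {len(joined)} rows for {joined['species'].nunique()} species "
      "(species repeat across categories)")
try:
    assert_pgls_safe(joined)
except ValueError as err:
    print(f"pgls refused, as intended: {str(err)[:60]}...")

# shape ~ habitat, ols on the duplicated-species table
subset = cm.phylogenetic_subset(configs, seed=5)
ali = cm.gpa(subset)
flat, species = ali.species_matrix()
shape = pd.DataFrame(flat, index=species)
hab = joined[joined["category_type"] == "habitat"]
hab = hab[hab["species"].isin(species)]
fit = cm.rrpp_lm(shape.loc[hab["species"]].to_numpy(), "category",
                 hab[["category"]].reset_index(drop=True), n_perm=499, seed=5)
print("\nshape ~ habitat (ols):")
print(fit.anova_table().round(3))
# Habitat classes were not used to generate shape, so P should be large.
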