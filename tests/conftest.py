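import numpy as np
import pandas as pd
import pytest

from craniomorph import (
    LandmarkConfiguration,
    SimulationSpec,
    gpa,
    prune_and_match,
    phylogenetic_subset,
    simulate_landmark_dataset,
)
from craniomorph.io import default_landmark_labels


def make_config(coords, specimen_id="s1", species="spA", missing=None, **kw):
    coords = np.asarray(coords, float)
    k = coords.shape[0]
    mask = np.zeros(k, bool)
    if missing is not None:
        mask[np.asarray(missing)] = True
    return LandmarkConfiguration(
        specimen_id=specimen_id, species=species, coords=coords,
        landmark_labels=default_landmark_labels(k), missing_mask=mask, **kw,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """24 species / 30 specimens with the default generating structure."""
    spec = SimulationSpec(n_species=24, n_multi_species=6, seed=11)
    configs, table, truth = simulate_landmark_dataset(spec)
    return configs, table, truth


@pytest.fixture(scope="session")
def small_species_alignment(small_dataset):
    """One specimen per species, superimposed, with matching pruned tree."""
    configs, table, truth = small_dataset
    subset = phylogenetic_subset(configs, seed=5)
    ali = gpa(subset)
    flat, species = ali.species_matrix()
    tree = prune_and_match(truth["tree"], species)
    Y = pd.DataFrame(flat, index=species)
    data = table.set_index("species").loc[species].copy()
    data["size"] = ali.log_centroid_size
    return ali, Y, tree, data


@pytest.fixture(scope="session")
def default_dataset():
    """The full-size default fixture: 96 species, 141 specimens."""
    spec = SimulationSpec(seed=7)
    return simulate_landmark_dataset(spec)
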