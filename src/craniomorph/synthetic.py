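"""Synthetic datasets with the statistical structure the analyses assume.

The generator emulates the structure of the study system: ~141 crania from
96 species (1-3 specimens each, most singletons), 53 landmarks on a
bilaterally symmetric template, a dated ultrametric phylogeny, Brownian
shape evolution sharing a size-shape allometric axis, optional planted
modular covariance among landmarks, intraspecific/measurement noise, and
gridded occurrence tables with habitat and net-primary-productivity values.

Shape evolution is simulated in the 3k-coordinate tangent space of a fixed
template scaled to unit centroid size; finished configurations are then
randomly rotated, translated and rescaled before being handed to the
readers/GPA so that superimposition is genuinely exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import dendropy

from .io import LandmarkConfiguration
from .trees import node_depths

HABITAT_TYPES = ("DXS", "MGS", "DBF", "MBF", "GSS")

# ---------------------------------------------------------------------------
# template cranium
#
# 53 landmarks: 1-22 right lateral, 23-44 left lateral (mirror of 1-22 in x),
# 45-53 midline (x = 0). Units are mm; the form is an elongated, bilaterally
# symmetric polyhedral "cranium" (z anterior, y dorsal, x right) so that the
# one-sided subset, the facial-length landmarks (5, 13, 52) and the
# region-based module schemes are all meaningful. The anatomy is schematic.

_RIGHT_LANDMARKS = [
    # (label, region, x, y, z)
    ("orbit_dorsal_rim", "orbit", 35.0, 60.0, 120.0),       # 1
    ("orbit_ventral_rim", "orbit", 38.0, 40.0, 118.0),      # 2
    ("orbit_anterior", "orbit", 30.0, 50.0, 130.0),         # 3
    ("orbit_posterior", "orbit", 40.0, 50.0, 105.0),        # 4
    ("orbit_anteriormost", "orbit", 28.0, 48.0, 135.0),     # 5 facial-length anchor
    ("frontal_lateral", "frontal", 25.0, 72.0, 100.0),      # 6
    ("frontal_posterior", "frontal", 20.0, 75.0, 80.0),     # 7
    ("nasal_lateral_ant", "nasal", 12.0, 55.0, 170.0),      # 8
    ("nasal_lateral_post", "nasal", 15.0, 60.0, 145.0),     # 9
    ("orbit_rim_dorsal2", "orbit", 33.0, 62.0, 112.0),      # 10
    ("orbit_rim_ventral2", "orbit", 37.0, 38.0, 110.0),     # 11
    ("premaxilla_lateral", "premaxilla", 10.0, 15.0, 190.0),  # 12
    ("premaxilla_anterior", "premaxilla", 6.0, 10.0, 198.0),  # 13 facial-length anchor
    ("zygomatic_process_ant", "temporal", 42.0, 35.0, 90.0),  # 14
    ("zygomatic_process_post", "temporal", 40.0, 33.0, 70.0),  # 15
    ("temporal_squamosal", "temporal", 35.0, 45.0, 55.0),   # 16
    ("maxilla_toothrow_ant", "maxilla", 18.0, 8.0, 150.0),  # 17
    ("maxilla_toothrow_post", "maxilla", 22.0, 8.0, 110.0),  # 18
    ("maxilla_lateral", "maxilla", 20.0, 25.0, 140.0),      # 19
    ("palatine_lateral", "palatine", 15.0, 5.0, 100.0),     # 20
    ("occipital_lateral", "occipital", 25.0, 40.0, 15.0),   # 21
    ("paroccipital_process", "basioccipital", 18.0, 10.0, 10.0),  # 22
]

_MIDLINE_LANDMARKS = [
    ("nasion", "nasal", 0.0, 70.0, 140.0),                  # 45
    ("frontal_midline", "frontal", 0.0, 78.0, 95.0),        # 46
    ("vault_midline", "occipital", 0.0, 70.0, 40.0),        # 47
    ("opisthion", "occipital", 0.0, 35.0, 5.0),             # 48
    ("basion", "basioccipital", 0.0, 12.0, 8.0),            # 49
    ("basisphenoid", "basioccipital", 0.0, 8.0, 60.0),      # 50
    ("palatine_midline", "palatine", 0.0, 2.0, 95.0),       # 51
    ("ventral_cranial_post", "basioccipital", 0.0, 10.0, 2.0),  # 52 facial-length anchor
    ("prosthion", "premaxilla", 0.0, 5.0, 200.0),           # 53
]


def template_cranium() -> tuple[np.ndarray, list[str], list[str]]:
    """Return (coords (53, 3) in mm, labels, anatomical regions)."""
    coords, labels, regions = [], [], []
    for name, region, x, y, z in _RIGHT_LANDMARKS:
        coords.append((x, y, z)); labels.append(name + "_R"); regions.append(region)
    for name, region, x, y, z in _RIGHT_LANDMARKS:
        coords.append((-x, y, z)); labels.append(name + "_L"); regions.append(region)
    for name, region, x, y, z in _MIDLINE_LANDMARKS:
        coords.append((x, y, z)); labels.append(name); regions.append(region)
    return np.array(coords, float), labels, regions


def symmetric_subset_regions() -> list[str]:
    """Regions of the 31 landmarks retained by the one-sided subset."""
    _, _, regions = template_cranium()
    return [regions[i] for i in range(53) if not 22 <= i <= 43]


# ---------------------------------------------------------------------------
# simulation spec


@dataclass
class SimulationSpec:
    """Generating parameters for a synthetic landmark dataset.

    Defaults reproduce the study conditions: 96 species, 141 specimens
    (45 species carry one extra specimen), 53 landmarks, tree root at
    ~15 Myr, Brownian shape rate giving per-coordinate tip SD ~ 0.01 shape
    units, log-size BM with tip SD ~ 0.5 and a shared allometric axis
    accounting for roughly a tenth of shape variance.
    """

    n_species: int = 96
    n_specimens_per_species: tuple[int, int] = (1, 2)
    n_multi_species: int = 45
    k_landmarks: int = 53
    root_age: float = 15.0                      # Myr
    bm_rate: float = 0.01 ** 2 / 15.0           # per-coordinate shape variance per Myr
    size_rate: float = 0.5 ** 2 / 15.0          # log-size variance per Myr
    root_log_size: float = 5.0                  # log mm, centroid size ~ 150 mm
    allometry_vector: np.ndarray | None = None  # unit vector, length 3k
    allometry_strength: float = 0.08            # shape change per unit log size
    module_assignment: dict | None = None       # 1-based landmark -> module label
    within_module_corr: float = 0.0
    between_module_corr: float = 0.0
    intraspecific_sd: float = 0.003             # shape units per coordinate
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.between_module_corr <= self.within_module_corr <= 1):
            raise ValueError("need 0 <= between_module_corr <= within_module_corr <= 1")
        if self.k_landmarks < 4:
            raise ValueError("template needs k >= 4")


def shape_tangent_projector(template_unit: np.ndarray):
    """Project 3k vectors into the shape tangent space at the template.

    Removes the seven directions a similarity transform can absorb —
    per-axis translation (3), infinitesimal rotation (3) and uniform
    scaling (1) — so a planted deformation survives superimposition.
    """
    k = template_unit.shape[0]
    basis = []
    for ax in range(3):
        e = np.zeros((k, 3))
        e[:, ax] = 1.0
        basis.append(e.ravel())
    gens = [np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], float),
            np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0]], float),
            np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], float)]
    for A in gens:
        basis.append((template_unit @ A.T).ravel())
    basis.append(template_unit.ravel())
    B = np.stack(basis, axis=1)
    Q, _ = np.linalg.qr(B)

    def project(v: np.ndarray) -> np.ndarray:
        return v - Q @ (Q.T @ v)

    return project


def default_allometry_vector(template_unit: np.ndarray) -> np.ndarray:
    """A fixed, unit-norm allometric axis: facial elongation with size.

    Anterior landmarks displace forward and ventrally relative to the
    braincase, echoing the craniofacial allometry of large herbivores.
    The raw deformation is projected into the shape tangent space (its
    translation/rotation/scale components would otherwise be removed by
    superimposition) and normalized.
    """
    k = template_unit.shape[0]
    z = template_unit[:, 2]
    w = (z - z.mean())
    w = w / np.abs(w).max()
    v = np.zeros((k, 3))
    v[:, 2] = 0.8 * w          # elongate along the facial axis
    v[:, 1] = -0.3 * w ** 2    # drop the rostrum
    v = shape_tangent_projector(template_unit)(v.ravel())
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# trees


def simulate_tree(n_tips: int, birth_rate: float = 0.3, seed: int = 0,
                  root_age: float | None = None) -> dendropy.Tree:
    """Seeded pure-birth (Yule) tree; optionally rescaled to a root age.

    Ultrametric by construction: all tips end at the stopping time.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    # grow: each active lineage carries its birth time
    tree.seed_node.birth_time = 0.0
    active = [tree.seed_node]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(rng.integers(len(active)))
        node.edge.length = t - node.birth_time
        for _ in range(2):
            child = node.new_child()
            child.birth_time = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    for i, node in enumerate(active):
        node.edge.length = t_end - node.birth_time
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(f"sp{str(i + 1).zfill(3)}")
    tree.seed_node.edge.length = None
    if root_age is not None:
        from .trees import root_height
        scale = root_age / root_height(tree)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    return tree


def _chol_psd(M: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(M)
        if vals.min() < -1e-8 * max(vals.max(), 1.0):
            raise ValueError("rate matrix is not positive semi-definite")
        vals = np.clip(vals, 0.0, None)
        return vecs * np.sqrt(vals)


def simulate_bm_traits(tree: dendropy.Tree, rate_matrix: np.ndarray,
                       root_state: np.ndarray | float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Multivariate Brownian tip data: vec(Y) ~ N(root, C (x) R).

    ``rate_matrix`` R is the p x p per-Myr trait covariance; C is the
    shared-path-length matrix of the tree. Returns species x p DataFrame.
    """
    from .trees import vcv_matrix

    R = np.atleast_2d(np.asarray(rate_matrix, float))
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("rate matrix must be symmetric")
    C, labels = vcv_matrix(tree)
    rng = np.random.default_rng(seed)
    Lc = _chol_psd(C)
    Lr = _chol_psd(R)
    Z = rng.standard_normal((C.shape[0], R.shape[0]))
    Y = Lc @ Z @ Lr.T + np.atleast_1d(np.asarray(root_state, float))[None, :]
    return pd.DataFrame(Y, index=labels, columns=[f"trait{j + 1}" for j in range(R.shape[0])])


# ---------------------------------------------------------------------------
# full landmark dataset


def block_correlation_matrix(k_landmarks: int, module_assignment: dict | None,
                             within: float, between: float) -> np.ndarray:
    """3k x 3k correlation with uniform within/between-module structure.

    ``module_assignment`` maps 1-based landmark numbers to module labels;
    all three coordinates of a landmark belong to its module. With no
    assignment the identity is returned.
    """
    q = 3 * k_landmarks
    if module_assignment is None or within == between == 0.0:
        return np.eye(q)
    labels = [module_assignment[i + 1] for i in range(k_landmarks)]
    coord_labels = np.repeat(labels, 3)
    same = coord_labels[:, None] == coord_labels[None, :]
    R = np.where(same, within, between)
    np.fill_diagonal(R, 1.0)
    return R


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(A)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _assign_tribes(tree: dendropy.Tree, n_tribes: int = 12) -> dict[str, str]:
    """Partition tips into named clades by repeatedly splitting the largest."""
    clades = [c for c in tree.seed_node.child_nodes()]
    while len(clades) < n_tribes:
        sizes = [len(c.leaf_nodes()) for c in clades]
        i = int(np.argmax(sizes))
        if sizes[i] <= 2:
            break
        node = clades.pop(i)
        kids = node.child_nodes()
        if not kids:
            clades.append(node)
            break
        clades.extend(kids)
    clades.sort(key=lambda c: min(lf.taxon.label for lf in c.leaf_nodes()))
    out = {}
    for t, clade in enumerate(clades):
        for leaf in clade.leaf_nodes():
            out[leaf.taxon.label] = f"tribe{str(t + 1).zfill(2)}"
    return out


def simulate_landmark_dataset(
    spec: SimulationSpec, tree: dendropy.Tree | None = None
) -> tuple[list[LandmarkConfiguration], pd.DataFrame, dict]:
    """Simulate specimens, species table and return the generating truth.

    Per species: log centroid size evolves by univariate BM; shape (in the
    unit-size template tangent space) is template + allometry * (log size -
    mean) + a multivariate BM deviation whose rate matrix carries the
    planted module structure. Per specimen, iid Gaussian coordinate noise
    is added, then the configuration is scaled to its size and arbitrarily
    rotated and translated.
    """
    from .trees import vcv_matrix

    rng = np.random.default_rng(spec.seed)
    if tree is None:
        tree = simulate_tree(spec.n_species, seed=int(rng.integers(2 ** 31)),
                             root_age=spec.root_age)
    template, labels, regions = template_cranium()
    if spec.k_landmarks != template.shape[0]:
        raise ValueError("only the 53-landmark template is currently shipped")
    template = template - template.mean(axis=0)
    template_unit = template / np.sqrt((template ** 2).sum())
    k = template.shape[0]
    q = 3 * k

    C, species = vcv_matrix(tree)
    n = len(species)
    Lc = _chol_psd(C)

    # log centroid size: univariate BM
    log_cs = spec.root_log_size + Lc @ rng.standard_normal(n) * np.sqrt(spec.size_rate)

    # shape deviations: matrix-normal BM with block-correlated rate matrix
    Rcorr = block_correlation_matrix(k, spec.module_assignment,
                                     spec.within_module_corr, spec.between_module_corr)
    Lr = _chol_psd(Rcorr * spec.bm_rate)
    D = Lc @ rng.standard_normal((n, q)) @ Lr.T

    allo = spec.allometry_vector
    if allo is None:
        allo = default_allometry_vector(template_unit)
    else:
        allo = shape_tangent_projector(template_unit)(np.asarray(allo, float))
    allo = allo / np.linalg.norm(allo)

    centered_size = log_cs - log_cs.mean()
    species_shapes = (
        template_unit.ravel()[None, :]
        + spec.allometry_strength * centered_size[:, None] * allo[None, :]
        + D
    )

    # specimen counts: singletons plus extras for a seeded subset of species
    counts = np.ones(n, dtype=int)
    multi = rng.choice(n, size=min(spec.n_multi_species, n), replace=False)
    lo, hi = spec.n_specimens_per_species
    counts[multi] = rng.integers(max(lo, 2), hi + 1, size=multi.size)

    # species metadata
    tribes = _assign_tribes(tree)
    root_children = tree.seed_node.child_nodes()
    big = max(root_children, key=lambda c: len(c.leaf_nodes()))
    antilopinae = {lf.taxon.label for lf in big.leaf_nodes()}
    diets = ("browser", "grazer", "mixed", "frugivore")
    tribe_names = sorted(set(tribes.values()))
    tribe_diet = {t: diets[i % 4] for i, t in enumerate(tribe_names)}
    species_diet = {}
    for sp in species:
        if rng.random() < 0.8:
            species_diet[sp] = tribe_diet[tribes[sp]]
        else:
            species_diet[sp] = diets[rng.integers(4)]
    # hypsodonty: positive BM-like trait, available for a 58-species subset
    hyps_raw = Lc @ rng.standard_normal(n) * np.sqrt(0.4 ** 2 / spec.root_age)
    hypsodonty = np.exp(0.6 + hyps_raw)
    has_hyps = set(rng.choice(n, size=min(58, n), replace=False).tolist())
    body_mass = np.exp(-10.5 + 3.0 * log_cs + rng.normal(0, 0.15, n))  # kg, ~ cs^3

    female_species = set(rng.choice(n, size=min(5, n), replace=False).tolist())

    configs: list[LandmarkConfiguration] = []
    for i, sp in enumerate(species):
        for rep in range(counts[i]):
            shape = species_shapes[i].reshape(k, 3).copy()
            if spec.intraspecific_sd > 0:
                shape += rng.normal(0.0, spec.intraspecific_sd, (k, 3))
            coords = shape * np.exp(log_cs[i])
            coords = coords @ _random_rotation(rng).T + rng.uniform(-500, 500, 3)
            scan = "ct" if rng.random() < 0.3 else "surface"
            if counts[i] >= 2 and rep == 1:
                scan = "ct" if configs[-1].scan_type == "surface" else "surface"
            configs.append(LandmarkConfiguration(
                specimen_id=f"{sp}_{rep + 1}", species=sp, coords=coords,
                landmark_labels=list(labels),
                missing_mask=np.zeros(k, bool),
                sex="female" if i in female_species else "male",
                scan_type=scan,
            ))

    table = pd.DataFrame({
        "species": species,
        "tribe": [tribes[sp] for sp in species],
        "subfamily": ["Antilopinae" if sp in antilopinae else "Bovinae" for sp in species],
        "diet": [species_diet[sp] for sp in species],
        "hypsodonty": [hypsodonty[i] if i in has_hyps else np.nan for i in range(n)],
        "body_mass": body_mass,
    })
    truth = {
        "tree": tree,
        "log_centroid_size": pd.Series(log_cs, index=species),
        "species_shapes": species_shapes,
        "allometry_vector": allo,
        "allometry_strength": spec.allometry_strength,
        "bm_rate": spec.bm_rate,
        "size_rate": spec.size_rate,
        "module_assignment": spec.module_assignment,
        "template_unit": template_unit,
        "regions": regions,
        "specimen_counts": pd.Series(counts, index=species),
    }
    return configs, table, truth


# ---------------------------------------------------------------------------
# occurrence grids


def simulate_occurrence_grid(
    n_cells: int,
    species_pool,
    habitat_types=HABITAT_TYPES,
    npp_range: tuple[float, float] = (0.0, 1100.0),
    mean_richness: float = 8.0,
    min_richness: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Gridded occurrence table: one row per (cell, species).

    Cells carry a 1-degree lat/lon, a habitat class and an NPP value;
    species are drawn with geometrically skewed frequencies so that
    "top 20% most common" selections are meaningful.
    """
    species_pool = list(species_pool)
    if not species_pool:
        raise ValueError("empty species pool")
    rng = np.random.default_rng(seed)
    weights = 0.9 ** np.arange(len(species_pool))
    weights = weights / weights.sum()
    # habitat-specific species affinities (skewed and habitat-dependent)
    affinity = {h: weights[rng.permutation(len(species_pool))] for h in habitat_types}
    rows = []
    for c in range(n_cells):
        habitat = habitat_types[rng.integers(len(habitat_types))]
        lo, hi = npp_range
        npp = float(rng.uniform(lo, hi))
        richness = max(min_richness, int(rng.poisson(mean_richness)))
        richness = min(richness, len(species_pool))
        w = affinity[habitat]
        members = rng.choice(len(species_pool), size=richness, replace=False, p=w)
        lat = float(rng.integers(-35, 56))
        lon = float(rng.integers(-17, 141))
        for m in members:
            rows.append({
                "cell_id": f"cell{str(c + 1).zfill(4)}",
                "latitude": lat, "longitude": lon,
                "habitat": habitat, "npp": npp,
                "species": species_pool[m],
            })
    return pd.DataFrame(rows)
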