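"""Environmental covariates from gridded occurrence tables.

Occurrence tables are long-format DataFrames with one row per
(cell, species) and columns cell_id, latitude, longitude, habitat, npp,
species. Habitat classes follow the five-way scheme (DXS, MGS, DBF, MBF,
GSS); NPP is in trillions of kg of carbon per one-degree cell. Because a
species typically occurs in several habitats and NPP bins, the joined
analysis table intentionally duplicates species — which is why fits on it
must be ordinary least squares, never pgls.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

#: NPP bin edges from the original raster extraction, kept for reproducing
#: the original analysis when that extraction is supplied. Synthetic runs
#: compute their own equal-count quantile edges instead.
REFERENCE_NPP_EDGES = (0.0, 115.0, 320.0, 580.0, 1100.0)

REQUIRED_COLUMNS = ("cell_id", "habitat", "npp", "species")


def _check(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")


def filter_cells(table: pd.DataFrame, min_species: int = 4, min_cells: int = 40) -> pd.DataFrame:
    """Keep well-sampled cells in well-sampled habitats.

    Cells need at least ``min_species`` species; habitat classes then need
    strictly more than ``min_cells`` qualifying cells to be retained.
    """
    _check(table)
    rich = table.groupby("cell_id")["species"].nunique()
    good_cells = rich[rich >= min_species].index
    out = table[table["cell_id"].isin(good_cells)]
    cells_per_habitat = out.groupby("habitat")["cell_id"].nunique()
    good_habitats = cells_per_habitat[cells_per_habitat > min_cells].index
    return out[out["habitat"].isin(good_habitats)].reset_index(drop=True)


def habitat_faunal_lists(table: pd.DataFrame, top_fraction: float = 1.0) -> dict[str, list[str]]:
    """Per habitat, the most commonly occurring species.

    Species are ranked within each habitat by the number of occupied
    cells; the top ``top_fraction`` is retained with an inclusive tie
    rule — every species tied with the species at the cutoff rank stays.
    """
    _check(table)
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    lists: dict[str, list[str]] = {}
    for habitat, grp in table.groupby("habitat"):
        counts = grp.groupby("species")["cell_id"].nunique().sort_values(ascending=False)
        if counts.empty:
            raise ValueError(f"habitat {habitat} has no occurrences")
        if top_fraction == 1.0:
            keep = counts.index
        else:
            n_keep = max(1, math.ceil(top_fraction * len(counts)))
            cutoff = counts.iloc[n_keep - 1]
            keep = counts[counts >= cutoff].index
        lists[habitat] = sorted(keep)
    return lists


def npp_bins(table: pd.DataFrame, n_bins: int = 4) -> tuple[pd.Series, np.ndarray]:
    """Quantile NPP bins with equal cell counts (+-1).

    Returns (cell -> bin label Series, bin edges). Bins are labelled
    npp1..npp{n} from low to high productivity.
    """
    _check(table)
    cells = table.drop_duplicates("cell_id").set_index("cell_id")["npp"]
    if len(cells) < n_bins:
        raise ValueError(f"need >= {n_bins} cells")
    if cells.nunique() == 1:
        raise ValueError("constant NPP: bins undefined")
    labels = [f"npp{i + 1}" for i in range(n_bins)]
    binned, edges = pd.qcut(cells, q=n_bins, labels=labels, retbins=True, duplicates="drop")
    return binned.astype(str), edges


def join_covariates(
    species_table: pd.DataFrame,
    faunal_lists: dict[str, list[str]],
    bins: tuple[pd.Series, np.ndarray] | None = None,
    occurrence: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-format species x category table ready for ols fits.

    One row per (species, habitat) membership and, when bins plus the
    occurrence table are given, per (species, NPP bin). The result carries
    ``allow_pgls = False`` in ``attrs``: species are duplicated across
    categories, so phylogenetic fits are statistically invalid on it and
    :func:`assert_pgls_safe` will refuse them.
    """
    known = set(species_table["species"])
    rows = []
    unknown = set()
    for habitat, species in sorted(faunal_lists.items()):
        for sp in species:
            if sp not in known:
                unknown.add(sp)
                continue
            rows.append({"species": sp, "category_type": "habitat", "category": habitat})
    if bins is not None:
        if occurrence is None:
            raise ValueError("NPP bins need the occurrence table to map species to cells")
        cell_bin, _ = bins
        occ = occurrence.copy()
        occ["npp_bin"] = occ["cell_id"].map(cell_bin)
        for (sp, b), _g in occ.dropna(subset=["npp_bin"]).groupby(["species", "npp_bin"]):
            if sp not in known:
                unknown.add(sp)
                continue
            rows.append({"species": sp, "category_type": "npp", "category": b})
    if unknown:
        raise KeyError(f"species in occurrence data but not in species table: {sorted(unknown)}")
    out = pd.DataFrame(rows).merge(species_table, on="species", how="left")
    out.attrs["allow_pgls"] = False
    return out


def assert_pgls_safe(table: pd.DataFrame) -> None:
    """Refuse phylogenetic fits on tables with duplicated species rows."""
    if table.attrs.get("allow_pgls") is False or table["species"].duplicated().any():
        raise ValueError(
            "this table duplicates species across categories (a species can "
            "occupy several habitats/NPP bins); pgls assumes one tip per row — "
            "use an ols fit instead"
        )
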