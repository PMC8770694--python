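"""Ordination and tree-aware morphospace statistics.

PCA is the centered, unscaled decomposition of the flattened Procrustes
coordinates. Phylomorphospace scores project Brownian-motion ancestral
state estimates onto the tip-defined PC axes (ancestors do not influence
the axes). Distance from the morphospace mean is measured in the full
shape space, not a PC subspace, so it does not depend on how many
components are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .geometry import ProcrustesAlignment
from .trees import vcv_matrix, node_depths


@dataclass
class PCAResult:
    scores: np.ndarray            # (n, r)
    loadings: np.ndarray          # (q, r), orthonormal columns
    eigenvalues: np.ndarray       # (r,), non-increasing
    variance_fraction: np.ndarray  # (r,), sums to 1
    mean: np.ndarray              # (q,)
    row_labels: list[str]

    def reconstruct(self) -> np.ndarray:
        return self.mean + self.scores @ self.loadings.T

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.row_labels, columns=cols)


@dataclass
class MorphospaceScores:
    distance_from_mean: pd.Series      # per species, >= 0
    centrality: pd.Series              # 'central' | 'peripheral', equal split

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance_from_mean": self.distance_from_mean,
                             "centrality": self.centrality})


def pca(data: ProcrustesAlignment | np.ndarray, row_labels: list[str] | None = None) -> PCAResult:
    """Centered, unscaled PCA of flattened shape coordinates.

    Scores fully reconstruct the data (all min(n-1, q) components kept);
    eigenvalues are the covariance-matrix eigenvalues (SS / (n - 1)).
    """
    if isinstance(data, ProcrustesAlignment):
        X = data.flat()
        row_labels = list(data.specimen_ids)
    else:
        X = np.asarray(data, float)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
        if row_labels is None:
            row_labels = [f"row{i + 1}" for i in range(X.shape[0])]
    n, q = X.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 rows")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    r = min(n - 1, q)
    U, s, Vt = U[:, :r], s[:r], Vt[:r]
    eig = s ** 2 / (n - 1)
    total = eig.sum()
    frac = eig / total if total > 0 else np.zeros_like(eig)
    return PCAResult(scores=U * s, loadings=Vt.T, eigenvalues=eig,
                     variance_fraction=frac, mean=mean, row_labels=row_labels)


def ancestral_states_bm(tree, tip_values: pd.DataFrame) -> pd.DataFrame:
    """Maximum-likelihood Brownian-motion states for every internal node.

    Equivalent to branch-length-weighted squared-change parsimony: the
    estimates minimize sum over edges of (change)^2 / length. The root
    estimate is the GLS (phylogenetically weighted) mean of the tips.
    Internal nodes are labelled node1..node(m) in preorder, node1 = root.
    """
    tips = list(tip_values.index)
    C, order = vcv_matrix(tree, tips)
    Y = tip_values.to_numpy(dtype=float)
    Cinv = np.linalg.inv(C)
    one = np.ones((len(order), 1))
    mu = (one.T @ Cinv @ Y) / float((one.T @ Cinv @ one).item())  # (1, p)

    depths = node_depths(tree)
    # leaf label sets per node for MRCA-depth lookups
    leafsets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = {node.taxon.label}
        else:
            leafsets[node] = set().union(*(leafsets[c] for c in node.child_nodes()))
    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    idx = {lab: i for i, lab in enumerate(order)}
    Cnt = np.zeros((len(internal), len(order)))
    for r_i, node in enumerate(internal):
        # MRCA(node, tip) = deepest ancestor-or-self of node containing tip
        chain = []
        cur = node
        while cur is not None:
            chain.append(cur)
            cur = cur.parent_node
        for lab in order:
            for anc in chain:
                if lab in leafsets[anc]:
                    Cnt[r_i, idx[lab]] = depths[anc]
                    break
    anc = mu + Cnt @ Cinv @ (Y - mu)
    names = [f"node{i + 1}" for i in range(len(internal))]
    return pd.DataFrame(anc, index=names, columns=tip_values.columns)


def phylomorphospace_scores(pca_result: PCAResult, tree, tip_values: pd.DataFrame) -> pd.DataFrame:
    """Project BM ancestral coordinate estimates onto tip-defined PC axes."""
    anc = ancestral_states_bm(tree, tip_values)
    return pd.DataFrame(
        (anc.to_numpy() - pca_result.mean) @ pca_result.loadings,
        index=anc.index,
        columns=[f"PC{i + 1}" for i in range(pca_result.loadings.shape[1])],
    )


def distance_from_mean(Y: np.ndarray | pd.DataFrame, species: list[str] | None = None) -> MorphospaceScores:
    """Euclidean distance of each species from the morphospace mean.

    Species are split into equal (+-1) 'central' / 'peripheral' halves by
    the median distance; ties at the boundary are broken by species-name
    order so the partition is deterministic.
    """
    if isinstance(Y, pd.DataFrame):
        species = list(Y.index)
        Y = Y.to_numpy(dtype=float)
    else:
        Y = np.asarray(Y, float)
        if Y.ndim == 3:
            Y = Y.reshape(Y.shape[0], -1)
        if species is None:
            species = [f"row{i + 1}" for i in range(Y.shape[0])]
    d = np.linalg.norm(Y - Y.mean(axis=0), axis=1)
    ser = pd.Series(d, index=species, name="distance_from_mean")
    order = sorted(range(len(species)), key=lambda i: (d[i], species[i]))
    n_central = len(species) // 2
    cats = np.empty(len(species), dtype=object)
    for rank, i in enumerate(order):
        cats[i] = "central" if rank < n_central else "peripheral"
    return MorphospaceScores(distance_from_mean=ser,
                             centrality=pd.Series(cats, index=species, name="centrality"))


def upgma_phenogram(data: ProcrustesAlignment | np.ndarray, labels: list[str] | None = None):
    """UPGMA (average-linkage) clustering on Euclidean shape distances.

    Returns (linkage matrix, labels). The linkage's third column holds the
    between-cluster average distances at each merge; the ultrametric tree
    height of a merge is half that distance.
    """
    if isinstance(data, ProcrustesAlignment):
        X = data.flat()
        labels = list(data.specimen_ids)
    else:
        X = np.asarray(data, float)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
        if labels is None:
            labels = [f"row{i + 1}" for i in range(X.shape[0])]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    Z = hierarchy.linkage(pdist(X), method="average")
    return Z, labels


def upgma_from_distances(D: np.ndarray, labels: list[str]):
    """UPGMA directly from a square distance matrix."""
    Z = hierarchy.linkage(squareform(np.asarray(D, float), checks=False), method="average")
    return Z, labels


def upgma_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage as a Newick string (heights = distance / 2)."""
    tree = hierarchy.to_tree(Z)

    def render(node) -> tuple[str, float]:
        if node.is_leaf():
            return labels[node.id], 0.0
        left, hl = render(node.left)
        right, hr = render(node.right)
        h = node.dist / 2.0
        return f"({left}:{h - hl:.6g},{right}:{h - hr:.6g})", h

    body, _ = render(tree)
    return body + ";"


def cluster_sisters(Z: np.ndarray, labels: list[str], a: str, b: str) -> bool:
    """True if leaves a and b are merged directly with each other."""
    ia, ib = labels.index(a), labels.index(b)
    return any((int(row[0]) == ia and int(row[1]) == ib) or
               (int(row[0]) == ib and int(row[1]) == ia) for row in Z)
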