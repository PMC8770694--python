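"""Phylogeny handling: Newick I/O, pruning, Brownian-motion covariance structure.

Trees are plain :class:`dendropy.Tree` objects with branch lengths in Myr.
Everything downstream (pgls, phylogenetic signal, rates, contrasts) consumes
the matrices built here, so tip ordering is always explicit.
"""

from __future__ import annotations

import numpy as np
import dendropy


class TreeFormatError(ValueError):
    """Raised for unparseable trees or trees lacking branch lengths."""


class TipMismatchError(KeyError):
    """Raised when requested species are absent from a tree."""


def read_tree(path) -> dendropy.Tree:
    """Read a rooted Newick tree; every non-root edge must carry a length."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeFormatError(f"could not parse Newick file {path}: {exc}") from exc
    _require_branch_lengths(tree)
    return tree


def read_tree_string(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:
        raise TreeFormatError(f"could not parse Newick string: {exc}") from exc
    _require_branch_lengths(tree)
    return tree


def _require_branch_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise TreeFormatError(
                f"edge above {_node_name(edge.head_node)} has no branch length"
            )
        if edge.length < 0:
            raise TreeFormatError(
                f"negative branch length above {_node_name(edge.head_node)}"
            )


def _node_name(node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return f"<internal node {id(node)}>"


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def prune_and_match(tree: dendropy.Tree, species: list[str]) -> dendropy.Tree:
    """Prune to exactly the requested tips, preserving patristic distances.

    Degree-2 nodes created by pruning are suppressed with their branch
    lengths summed.
    """
    have = set(tip_labels(tree))
    missing = sorted(set(species) - have)
    if missing:
        raise TipMismatchError(f"species absent from tree: {', '.join(missing)}")
    pruned = tree.extract_tree_with_taxa_labels(labels=set(species))
    pruned.taxon_namespace = pruned.taxon_namespace  # keep own namespace
    return pruned


def node_depths(tree: dendropy.Tree) -> dict:
    """Depth (distance from root) of every node."""
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def root_height(tree: dendropy.Tree) -> float:
    depths = node_depths(tree)
    return max(depths[leaf] for leaf in tree.leaf_node_iter())


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    depths = node_depths(tree)
    leaf_depths = np.array([depths[leaf] for leaf in tree.leaf_node_iter()])
    height = leaf_depths.max()
    if height == 0:
        return True
    return bool(np.ptp(leaf_depths) <= rel_tol * height)


def vcv_matrix(tree: dendropy.Tree, order: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix C: C[i, j] = shared path length from root.

    Returns (C, labels); ``order`` fixes the row order, defaulting to the
    tree's leaf iteration order.
    """
    depths = node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    if order is None:
        order = labels
    missing = sorted(set(order) - set(labels))
    if missing:
        raise TipMismatchError(f"species absent from tree: {', '.join(missing)}")
    index = {lab: i for i, lab in enumerate(order)}
    n = len(order)
    C = np.zeros((n, n))
    # leaf sets per internal node, post-order: shared depth of a pair is the
    # depth of the shallowest node separating them into different children
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._leafset = [node.taxon.label]
            if node.taxon.label in index:
                i = index[node.taxon.label]
                C[i, i] = depths[node]
            continue
        children = node.child_nodes()
        sets = [ch._leafset for ch in children]
        d = depths[node]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                for la in sets[a]:
                    if la not in index:
                        continue
                    i = index[la]
                    for lb in sets[b]:
                        if lb not in index:
                            continue
                        j = index[lb]
                        C[i, j] = C[j, i] = d
        node._leafset = [x for s in sets for x in s]
    for node in tree.postorder_node_iter():
        if hasattr(node, "_leafset"):
            del node._leafset
    return C, list(order)


def inv_sqrt_psd(C: np.ndarray, rcond: float = 1e-12) -> np.ndarray:
    """Symmetric inverse square root of a PSD matrix via eigendecomposition."""
    vals, vecs = np.linalg.eigh(C)
    cutoff = rcond * vals.max()
    inv = np.where(vals > cutoff, 1.0 / np.sqrt(np.clip(vals, cutoff, None)), 0.0)
    return (vecs * inv) @ vecs.T


def phylo_gls_mean(C: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """GLS (phylogenetically weighted) mean of tip data under BM."""
    Cinv = np.linalg.inv(C)
    one = np.ones((C.shape[0], 1))
    w = Cinv @ one / float((one.T @ Cinv @ one).item())
    return (Y.T @ w).ravel()


def pic_contrasts(tree: dendropy.Tree, values: np.ndarray, order: list[str]) -> np.ndarray:
    """Felsenstein's phylogenetically independent contrasts, standardized.

    ``values`` is species x p in the order given; returns (n_tips - 1) x p.
    Polytomies are resolved arbitrarily with zero-length branches.
    """
    work = tree.clone(depth=1)
    work.resolve_polytomies()
    index = {lab: i for i, lab in enumerate(order)}
    n, p = values.shape
    contrasts = []
    node_val: dict = {}
    node_bl: dict = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            if lab not in index:
                raise TipMismatchError(f"no data for tip {lab}")
            node_val[node] = values[index[lab]].astype(float)
            node_bl[node] = float(node.edge.length or 0.0)
            continue
        children = node.child_nodes()
        if len(children) == 1:  # degree-2 passthrough
            child = children[0]
            node_val[node] = node_val[child]
            node_bl[node] = float(node.edge.length or 0.0) + node_bl[child]
            continue
        c1, c2 = children
        b1, b2 = node_bl[c1], node_bl[c2]
        denom = b1 + b2
        if denom <= 0:
            denom = 1e-12
        contrasts.append((node_val[c1] - node_val[c2]) / np.sqrt(denom))
        node_val[node] = (b2 * node_val[c1] + b1 * node_val[c2]) / denom
        node_bl[node] = float(node.edge.length or 0.0) + b1 * b2 / denom
    return np.array(contrasts)


def patristic_matrix(tree: dendropy.Tree, order: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Tip-to-tip path-length matrix."""
    depths = node_depths(tree)
    C, labels = vcv_matrix(tree, order)
    d = np.diag(C)
    return d[:, None] + d[None, :] - 2 * C, labels
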