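"""Module schemes, association matrices, CR, EMMLi and gap-statistic discovery."""

import numpy as np
import pandas as pd
import pytest

from craniomorph import (
    ModuleScheme, anatomical_schemes, congruence_matrix, pic_covariance_matrix,
    kmeans_gap_modules, covariance_ratio, emmli_compare, modularity_contrast,
)
from craniomorph.modularity import SchemeError, covariance_block_distances
from craniomorph.synthetic import block_correlation_matrix
from craniomorph.trees import read_tree_string, pic_contrasts


def planted_scheme(k=31, split=15):
    return ModuleScheme("planted", {i + 1: ("A" if i < split else "B") for i in range(k)})


def modular_data(n=96, k=31, within=0.7, between=0.1, seed=0, split=15):
    scheme = planted_scheme(k, split)
    R = block_correlation_matrix(k, scheme.assignment, within, between)
    L = np.linalg.cholesky(R + 1e-10 * np.eye(3 * k))
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, 3 * k)) @ L.T, scheme


# --- schemes ---------------------------------------------------------------


def test_anatomical_schemes_cover_all_landmarks():
    schemes = anatomical_schemes()
    names = {s.name: s for s in schemes}
    assert set(names) == {"Mammalia 2", "Tripartite", "Four", "Element", "Mammalia 6"}
    assert names["Element"].n_modules == 9
    for s in schemes:
        s.validate_for_cr(31)  # raises on gaps or undersized modules


def test_scheme_rejects_singleton_modules():
    scheme = ModuleScheme("bad", {1: "a", 2: "a", 3: "b"})
    with pytest.raises(SchemeError, match="fewer than 2"):
        scheme.validate_for_cr(3)


def test_scheme_requires_full_assignment():
    scheme = ModuleScheme("gap", {1: "a", 2: "a", 4: "b", 5: "b"})
    with pytest.raises(SchemeError, match="assigned"):
        scheme.validate_for_cr(5)


# --- congruence ------------------------------------------------------------


def test_congruence_duplicated_landmark_is_one():
    rng = np.random.default_rng(1)
    A = rng.normal(size=(20, 5, 3))
    A[:, 4] = A[:, 0]
    M = congruence_matrix(A)
    assert M[0, 4] == pytest.approx(1.0)
    np.testing.assert_allclose(M, M.T)
    np.testing.assert_allclose(np.diag(M), 1.0)


def test_congruence_independent_blocks_near_zero():
    rng = np.random.default_rng(2)
    A = rng.normal(size=(400, 4, 3))
    M = congruence_matrix(A, center=True)
    off = M[~np.eye(4, dtype=bool)]
    assert np.abs(off).max() < 0.12


# --- PIC-based matrices ----------------------------------------------------


def test_pic_contrasts_match_hand_computation():
    # ((A:1,B:1):0.5,C:2): first contrast (A-B)/sqrt(1+1); the AB node takes
    # value (A+B)/2 and branch 0.5 + (1*1)/(1+1) = 1, so the second contrast
    # is (AB-C)/sqrt(1+2)
    tree = read_tree_string("((A:1,B:1):0.5,C:2);")
    vals = np.array([[1.0], [3.0], [6.0]])
    U = pic_contrasts(tree, vals, ["A", "B", "C"])
    got = sorted(np.abs(U.ravel()))
    expected = sorted([abs(1.0 - 3.0) / np.sqrt(2.0),
                       abs(2.0 - 6.0) / np.sqrt(1.0 + 2.0)])
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_pic_distance_matrix_on_star_tree_matches_raw():
    n, k = 30, 6
    rng = np.random.default_rng(3)
    X = rng.normal(size=(n, 3 * k))
    tips = ",".join(f"t{i}:1.0" for i in range(n))
    tree = read_tree_string(f"({tips});")
    species = [f"t{i}" for i in range(n)]
    D_pic = pic_covariance_matrix(pd.DataFrame(X, index=species), tree)
    D_raw = covariance_block_distances(X, center=True)
    # contrasts on an equal-branch star are an orthonormal rotation of the
    # centered data, so the block covariances coincide exactly
    np.testing.assert_allclose(D_pic, D_raw, atol=1e-8)
    assert (D_pic >= -1e-12).all()


# --- covariance ratio ------------------------------------------------------


def test_cr_detects_planted_modules():
    X, scheme = modular_data(seed=4)
    res = covariance_ratio(X, scheme, n_perm=199, seed=4)
    assert res.CR < 1.0
    assert res.Z < -2.0
    assert res.P <= 0.05


def test_cr_null_brackets_one_on_nonmodular_data():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((96, 93))
    res = covariance_ratio(X, planted_scheme(), n_perm=199, seed=5)
    assert 0.85 < res.CR < 1.15
    assert abs(res.Z) < 2.0


def test_cr_invariant_to_module_relabeling_and_landmark_order():
    X, scheme = modular_data(seed=6)
    res1 = covariance_ratio(X, scheme, n_perm=9, seed=6)
    relabeled = ModuleScheme("swap", {i: {"A": "Z", "B": "Y"}[m]
                                      for i, m in scheme.assignment.items()})
    res2 = covariance_ratio(X, relabeled, n_perm=9, seed=6)
    assert res1.CR == pytest.approx(res2.CR, abs=1e-12)
    # permute whole landmarks consistently in data and scheme
    rng = np.random.default_rng(7)
    perm = rng.permutation(31)
    Xp = X.reshape(-1, 31, 3)[:, perm, :].reshape(-1, 93)
    scheme_p = ModuleScheme("perm", {j + 1: scheme.assignment[int(p) + 1]
                                     for j, p in enumerate(perm)})
    res3 = covariance_ratio(Xp, scheme_p, n_perm=9, seed=6)
    assert res3.CR == pytest.approx(res1.CR, abs=1e-12)


def test_phylogenetic_cr_equals_plain_cr_on_star_tree():
    X, scheme = modular_data(n=24, seed=8)
    species = [f"t{i}" for i in range(24)]
    tips = ",".join(f"{s}:1.0" for s in species)
    tree = read_tree_string(f"({tips});")
    plain = covariance_ratio(X - X.mean(axis=0), scheme, n_perm=9, seed=8)
    phylo = covariance_ratio(pd.DataFrame(X, index=species), scheme, n_perm=9,
                             seed=8, phylogenetic=True, tree=tree)
    assert phylo.CR == pytest.approx(plain.CR, abs=1e-8)


def test_cr_nine_module_scheme_reports_pairwise_matrix():
    rng = np.random.default_rng(9)
    X = rng.standard_normal((40, 93))
    res = covariance_ratio(X, anatomical_schemes()[3], n_perm=9, seed=9)
    assert res.pairwise.shape == (9, 9)
    np.testing.assert_allclose(res.pairwise, res.pairwise.T)


# --- gap statistic ---------------------------------------------------------


def test_gap_recovers_planted_partition():
    X, scheme = modular_data(within=0.8, between=0.0, seed=10)
    D = covariance_block_distances(X)
    found, gap = kmeans_gap_modules(D, k_max=6, B_reference=40, restarts=10, seed=10)
    assert gap.chosen_k == 2
    # exact partition recovery up to label swap
    got = np.array([found.assignment[i + 1] for i in range(31)])
    want = np.array([scheme.assignment[i + 1] for i in range(31)])
    agreement = max(np.mean((got == got[0]) == (want == want[0])), 0)
    assert agreement == 1.0
    assert np.all(np.diff(gap.W) <= 1e-9)


def test_gap_prefers_one_cluster_for_noise():
    rng = np.random.default_rng(11)
    chosen = []
    for rep in range(5):
        M = rng.standard_normal((31, 31))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        _, gap = kmeans_gap_modules(np.abs(M), k_max=5, B_reference=30,
                                    restarts=5, seed=100 + rep)
        chosen.append(gap.chosen_k)
    assert np.mean(np.array(chosen) == 1) >= 0.6


def test_gap_rejects_degenerate_matrix():
    with pytest.raises(ValueError, match="degenerate"):
        kmeans_gap_modules(np.ones((10, 10)), k_max=3, seed=0)


# --- EMMLi -----------------------------------------------------------------


def test_emmli_uniform_rho_prefers_single_model():
    rng = np.random.default_rng(12)
    k = 31
    z = 0.3 + rng.normal(0, 1.0 / np.sqrt(k - 3), size=(k, k))
    A = np.tanh((z + z.T) / 2)
    np.fill_diagonal(A, 1.0)
    res = emmli_compare(A, [planted_scheme()])
    assert res.best_model == "no modularity (single rho)"


def test_emmli_recovers_planted_two_module_structure():
    rng = np.random.default_rng(13)
    k = 31
    scheme = planted_scheme()
    labels = np.array([scheme.assignment[i + 1] for i in range(k)])
    true_z = np.where(labels[:, None] == labels[None, :], np.arctanh(0.6), np.arctanh(0.1))
    z = true_z + rng.normal(0, 1.0 / np.sqrt(k - 3), size=(k, k))
    A = np.tanh((z + z.T) / 2)
    np.fill_diagonal(A, 1.0)
    res = emmli_compare(A, [scheme])
    tab = res.table
    assert tab.loc["planted: within+between", "AICc"] < tab.loc["no modularity (single rho)", "AICc"]
    est = res.rho["planted: within+between"]
    assert est.loc["within A", "rho"] > 0.45
    assert est.loc["between (shared)", "rho"] < 0.3


def test_emmli_identical_trajectories_have_rho_near_one():
    rng = np.random.default_rng(14)
    A = np.full((6, 6), 0.999)
    np.fill_diagonal(A, 1.0)
    scheme = ModuleScheme("two", {i + 1: ("a" if i < 3 else "b") for i in range(6)})
    res = emmli_compare(A, [scheme])
    est = res.rho[res.best_model]
    assert (est["rho"] > 0.99).all()


def test_emmli_block_mle_matches_grid_search():
    # the closed-form block MLE (inverse Fisher of the mean z) against a
    # brute-force grid over rho
    from craniomorph.modularity import _block_loglik, _fisher_z
    rng = np.random.default_rng(15)
    zs = _fisher_z(rng.uniform(0.1, 0.7, size=25))
    n_eff = 31
    ll_closed, rho_closed = _block_loglik(zs, n_eff)
    var = 1.0 / (n_eff - 3)
    grid = np.linspace(-0.999, 0.999, 20001)
    lls = [-0.5 * len(zs) * np.log(2 * np.pi * var)
           - ((zs - np.arctanh(r)) ** 2).sum() / (2 * var) for r in grid]
    best = int(np.argmax(lls))
    assert rho_closed == pytest.approx(grid[best], abs=2e-4)
    assert ll_closed >= lls[best] - 1e-8


# --- modularity contrasts --------------------------------------------------


def test_contrast_of_duplicated_sample_is_zero():
    X, scheme = modular_data(n=40, seed=16)
    g = ["g1"] * 40 + ["g2"] * 40
    res = modularity_contrast(np.vstack([X, X]), scheme, g, n_perm=19, seed=16)
    assert res[("delta_Z", "g2")].loc["g1"] < 1.0


def test_contrast_detects_differential_modularity():
    Xa, scheme = modular_data(n=40, within=0.7, between=0.1, seed=17)
    rng = np.random.default_rng(18)
    Xb = rng.standard_normal((40, 93))
    g = ["modular"] * 40 + ["amorphous"] * 40
    res = modularity_contrast(np.vstack([Xa, Xb]), scheme, g, n_perm=99, seed=18)
    assert res[("P", "amorphous")].loc["modular"] <= 0.05
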