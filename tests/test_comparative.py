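"""Permutation ANOVA, phylogenetic signal, disparity, rates, regression scores."""

import numpy as np
import pandas as pd
import pytest

from craniomorph import (
    rrpp_lm, pairwise_groups, physignal_K, disparity_test, evol_rate_test,
    regression_score, simulate_tree, simulate_bm_traits,
)
from craniomorph.comparative import DesignError, parse_formula
from craniomorph.trees import read_tree_string


def star_tree(n, length=1.0):
    tips = ",".join(f"t{i}:{length}" for i in range(n))
    return read_tree_string(f"({tips});")


# --- formula / design ------------------------------------------------------


def test_formula_expansion():
    assert parse_formula("a * b") == ["a", "b", "a:b"]
    assert parse_formula("a + b + a:b") == ["a", "b", "a:b"]
    assert parse_formula("size") == ["size"]


def test_collinear_duplicate_predictor_is_named():
    rng = np.random.default_rng(0)
    data = pd.DataFrame({"x": rng.normal(size=20)})
    data["x2"] = data["x"] * 2.0
    with pytest.raises(DesignError, match="x2"):
        rrpp_lm(rng.normal(size=(20, 3)), "x + x2", data, n_perm=9, seed=0)


# --- RRPP core -------------------------------------------------------------


def test_univariate_f_matches_classical_anova():
    # hand-computable one-way ANOVA with 3 groups
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 7.0, 8.0, 10.0, 12.0])
    g = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    grand = y.mean()
    ss_between = sum(3 * (y[i:i + 3].mean() - grand) ** 2 for i in (0, 3, 6))
    ss_within = sum(((y[i:i + 3] - y[i:i + 3].mean()) ** 2).sum() for i in (0, 3, 6))
    f_classical = (ss_between / 2) / (ss_within / 6)

    fit = rrpp_lm(y[:, None], "group", pd.DataFrame({"group": g}), n_perm=99, seed=1)
    assert fit.F[0] == pytest.approx(f_classical, rel=1e-10)
    assert fit.SS[0] == pytest.approx(ss_between)
    assert fit.df[0] == 2 and fit.df_residual == 6


def test_sequential_ss_adds_up():
    rng = np.random.default_rng(2)
    data = pd.DataFrame({"x": rng.normal(size=30),
                         "g": rng.choice(list("ab"), 30)})
    Y = rng.normal(size=(30, 6))
    fit = rrpp_lm(Y, "x * g", data, n_perm=49, seed=2)
    assert fit.SS.sum() == pytest.approx(fit.SS_total - fit.SS_residual, abs=1e-8)
    assert fit.R2.sum() <= 1.0 + 1e-12


def test_p_floor_is_one_over_nperm_plus_one():
    rng = np.random.default_rng(3)
    x = rng.normal(size=40)
    Y = np.outer(x, np.ones(4)) + rng.normal(size=(40, 4)) * 0.01
    fit = rrpp_lm(Y, "x", pd.DataFrame({"x": x}), n_perm=99, seed=3)
    assert fit.P[0] == pytest.approx(1 / 100)


def test_z_monotone_in_p_within_fit():
    rng = np.random.default_rng(4)
    n = 60
    data = pd.DataFrame({
        "strong": rng.normal(size=n),
        "weak": rng.normal(size=n),
        "null": rng.normal(size=n),
    })
    Y = np.outer(data["strong"], np.ones(5)) + \
        0.25 * np.outer(data["weak"], np.ones(5)) + rng.normal(size=(n, 5))
    fit = rrpp_lm(Y, "strong + weak + null", data, n_perm=199, seed=4)
    order = np.argsort(fit.P)
    assert np.all(np.diff(fit.Z[order]) <= 0.0)


def test_ols_equals_pgls_on_equal_star_tree():
    rng = np.random.default_rng(5)
    n = 16
    tree = star_tree(n, length=2.0)
    species = [f"t{i}" for i in range(n)]
    data = pd.DataFrame({"x": rng.normal(size=n),
                         "g": rng.choice(list("ab"), n)}, index=species)
    Y = rng.normal(size=(n, 4))
    ols = rrpp_lm(Y, "x + g", data, n_perm=99, seed=6)
    pgls = rrpp_lm(Y, "x + g", data, tree=tree, n_perm=99, seed=6)
    np.testing.assert_allclose(ols.F, pgls.F, atol=1e-9)
    np.testing.assert_allclose(ols.SS / ols.SS_total, pgls.SS / pgls.SS_total, atol=1e-9)
    np.testing.assert_array_equal(ols.P, pgls.P)


# --- pairwise --------------------------------------------------------------


def test_pairwise_identical_groups_not_distinguished():
    rng = np.random.default_rng(7)
    base = rng.normal(size=(15, 6))
    Y = np.vstack([base, base])
    data = pd.DataFrame({"g": ["a"] * 15 + ["b"] * 15})
    fit = rrpp_lm(Y, "g", data, n_perm=99, seed=7)
    pw = pairwise_groups(fit, "g", n_perm=99, seed=7)
    assert pw.distance.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)
    assert pw.P.loc["a", "b"] > 0.5


def test_pairwise_detects_planted_shift():
    rng = np.random.default_rng(8)
    n_per = 15
    Y = rng.normal(size=(3 * n_per, 5))
    Y[:n_per] += 2.0  # group a shifted away from b and c
    data = pd.DataFrame({"g": ["a"] * n_per + ["b"] * n_per + ["c"] * n_per})
    fit = rrpp_lm(Y, "g", data, n_perm=199, seed=8)
    pw = pairwise_groups(fit, "g", n_perm=199, seed=8)
    assert pw.P.loc["a", "b"] <= 0.01
    assert pw.P.loc["a", "c"] <= 0.01
    assert pw.P.loc["b", "c"] > 0.1


def test_pairwise_slopes_equal_allometries_have_zero_angle():
    rng = np.random.default_rng(9)
    n = 40
    x = rng.normal(size=n)
    g = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    v = rng.normal(size=6)
    Y = np.outer(x, v) + rng.normal(size=(n, 6)) * 0.01
    data = pd.DataFrame({"x": x, "g": g})
    fit = rrpp_lm(Y, "x * g", data, n_perm=99, seed=9)
    pw = pairwise_groups(fit, "g", statistic="slope_angle_and_length", n_perm=99, seed=9)
    assert pw.angle.loc["a", "b"] < 2.0
    assert pw.P.loc["a", "b"] > 0.1


# --- phylogenetic signal ---------------------------------------------------


def test_k_near_one_under_brownian_motion():
    tree = simulate_tree(40, seed=10, root_age=10.0)
    ks = []
    for rep in range(30):
        Y = simulate_bm_traits(tree, np.eye(8), seed=100 + rep)
        ks.append(physignal_K(Y, tree, n_perm=1, seed=rep).K)
    assert 0.85 < np.mean(ks) < 1.15


def test_shuffled_tips_lose_signal():
    tree = simulate_tree(40, seed=11, root_age=10.0)
    Y = simulate_bm_traits(tree, np.eye(8), seed=12)
    shuffled = Y.copy()
    rng = np.random.default_rng(13)
    shuffled.index = list(np.array(Y.index)[rng.permutation(len(Y))])
    res = physignal_K(shuffled, tree, n_perm=199, seed=13)
    assert res.K < 0.7
    assert res.P > 0.05


def test_k_significance_detected_for_bm_data():
    tree = simulate_tree(40, seed=14, root_age=10.0)
    Y = simulate_bm_traits(tree, np.eye(8), seed=15)
    res = physignal_K(Y, tree, n_perm=199, seed=16)
    assert res.P <= 0.01


# --- disparity -------------------------------------------------------------


def test_disparity_identical_shapes_zero_variance():
    Y = np.tile(np.arange(6.0), (10, 1))
    Y2 = np.random.default_rng(17).normal(size=(10, 6))
    g = ["flat"] * 10 + ["noisy"] * 10
    res = disparity_test(np.vstack([Y, Y2]), g, n_perm=99, seed=17)
    assert res.variances["flat"] == pytest.approx(0.0, abs=1e-12)
    assert res.variances["noisy"] > 0


def test_disparity_variance_scales_with_noise():
    rng = np.random.default_rng(18)
    a = rng.normal(size=(50, 8))
    b = rng.normal(size=(50, 8)) * 2.0
    res = disparity_test(np.vstack([a, b]), ["a"] * 50 + ["b"] * 50,
                         n_perm=199, seed=18)
    ratio = res.variances["b"] / res.variances["a"]
    assert 3.2 < ratio < 4.8
    assert res.P.loc["a", "b"] <= 0.01


def test_disparity_excludes_singletons():
    rng = np.random.default_rng(19)
    Y = rng.normal(size=(11, 4))
    g = ["a"] * 5 + ["b"] * 5 + ["lonely"]
    with pytest.warns(UserWarning, match="lonely"):
        res = disparity_test(Y, g, n_perm=49, seed=19)
    assert "lonely" in res.excluded
    assert set(res.variances.index) == {"a", "b"}


# --- evolutionary rates ----------------------------------------------------


def test_rate_recovery_single_group():
    tree = simulate_tree(40, seed=20, root_age=1.0)
    true_rate = 2.0
    ests = []
    for rep in range(20):
        Y = simulate_bm_traits(tree, np.eye(5) * true_rate / 5, seed=200 + rep)
        res = evol_rate_test(Y, tree, pd.Series("all", index=Y.index),
                             n_sim=1, seed=rep)
        ests.append(res.rates["all"])
    est = np.mean(ests)
    se = np.std(ests, ddof=1) / np.sqrt(len(ests))
    assert abs(est - true_rate) < max(2 * se, 0.2 * true_rate)


def test_equal_rates_give_ratio_near_one():
    tree = simulate_tree(40, seed=21, root_age=1.0)
    Y = simulate_bm_traits(tree, np.eye(5), seed=22)
    species = list(Y.index)
    g = pd.Series(["g1" if i < 20 else "g2" for i in range(40)], index=species)
    res = evol_rate_test(Y, tree, g, n_sim=199, seed=23)
    assert res.ratio < 1.6
    assert res.P > 0.05


def test_quadrupled_rate_detected():
    tree = simulate_tree(48, seed=24, root_age=1.0)
    species = list(pd.Index([leaf for leaf in
                             (t.label for t in tree.taxon_namespace)]))
    g = pd.Series(["fast" if i < 24 else "slow" for i in range(48)], index=species)
    # simulate group-specific rates by scaling tip deviations per group
    Y = simulate_bm_traits(tree, np.eye(5), seed=25)
    Y = Y.loc[species]
    Y.loc[g == "fast"] *= 2.0  # variance x4 for the fast group
    res = evol_rate_test(Y, tree, g, n_sim=199, seed=26)
    assert res.ratio > 2.0
    assert res.P <= 0.05


# --- regression score ------------------------------------------------------


def test_regression_score_tracks_constructed_signal():
    rng = np.random.default_rng(27)
    n = 60
    x = rng.normal(size=n)
    v = rng.normal(size=12)
    v /= np.linalg.norm(v)
    Y = np.outer(x, v) + rng.normal(size=(n, 12)) * 0.1  # SNR ~ 10
    s = regression_score(Y, x)
    assert np.corrcoef(s, x)[0, 1] > 0.95
    # shuffling the predictor destroys the association with it
    xs = rng.permutation(x)
    s0 = regression_score(Y, xs)
    assert abs(np.corrcoef(s0, xs)[0, 1]) < 0.5


def test_regression_score_rotation_invariant():
    rng = np.random.default_rng(28)
    x = rng.normal(size=30)
    Y = np.outer(x, rng.normal(size=8)) + rng.normal(size=(30, 8))
    Q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
    np.testing.assert_allclose(regression_score(Y, x), regression_score(Y @ Q, x), atol=1e-9)


def test_regression_score_rejects_constant_x():
    with pytest.raises(ValueError, match="variance"):
        regression_score(np.zeros((5, 3)), np.ones(5))
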