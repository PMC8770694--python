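"""Permutational linear models and phylogenetic comparative statistics.

The workhorse is :func:`rrpp_lm`: multivariate linear models on shape with
sequential (Type I) sums of squares and significance from residual
randomization (RRPP) — for each term, residuals of the reduced model
(all preceding terms) are permuted, the statistic recomputed, and the
observed value ranked within its permutation distribution. Effect sizes
Z are standardized deviates of log F within that distribution.

Phylogenetic (pgls) fits transform response and design by the inverse
square root of the Brownian-motion covariance C implied by a dated tree,
making the errors exchangeable; on a star phylogeny with equal branch
lengths pgls and ols coincide exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import vcv_matrix, inv_sqrt_psd, phylo_gls_mean

__all__ = [
    "ModelFit", "PairwiseResult", "SignalResult", "DisparityResult", "RateResult",
    "rrpp_lm", "pairwise_groups", "physignal_K", "disparity_test",
    "evol_rate_test", "regression_score",
]


class DesignError(ValueError):
    """Rank-deficient or otherwise unusable model designs."""


# ---------------------------------------------------------------------------
# formula parsing and design construction


def parse_formula(rhs: str) -> list[str]:
    """Expand a right-hand-side formula into an ordered term list.

    Supports '+' separated terms, ':' interactions and 'a * b' crossing
    (expands to a + b + a:b). Main effects precede their interactions.
    """
    terms: list[str] = []

    def add(t: str):
        if t and t not in terms:
            terms.append(t)

    for chunk in rhs.split("+"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "*" in chunk:
            factors = [f.strip() for f in chunk.split("*")]
            for f in factors:
                add(f)
            add(":".join(factors))
        else:
            add(chunk)
    if not terms:
        raise DesignError(f"empty formula {rhs!r}")
    return terms


def _encode_main(data: pd.DataFrame, var: str) -> tuple[np.ndarray, int]:
    if var not in data.columns:
        raise DesignError(f"variable {var!r} not in data columns {list(data.columns)}")
    col = data[var]
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)[:, None], 1
    # treatment contrasts, alphabetical reference level
    levels = sorted(col.astype(str).unique())
    if len(levels) < 2:
        raise DesignError(f"factor {var!r} has a single level")
    dummies = np.column_stack([
        (col.astype(str) == lev).to_numpy(dtype=float) for lev in levels[1:]
    ])
    return dummies, len(levels) - 1


def build_design(data: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Design matrix (with leading intercept) and per-term column counts."""
    n = len(data)
    blocks = [np.ones((n, 1))]
    info: list[tuple[str, int]] = []
    mains: dict[str, np.ndarray] = {}
    for term in terms:
        parts = term.split(":")
        for p in parts:
            if p not in mains:
                mains[p], _ = _encode_main(data, p)
        block = mains[parts[0]]
        for p in parts[1:]:
            other = mains[p]
            block = np.concatenate([block[:, i:i + 1] * other for i in range(block.shape[1])], axis=1)
        blocks.append(block)
        info.append((term, block.shape[1]))
    X = np.concatenate(blocks, axis=1)
    # sequential rank check so aliased terms are named
    rank = 1
    col = 1
    for term, width in info:
        new_rank = np.linalg.matrix_rank(X[:, : col + width])
        if new_rank != rank + width:
            raise DesignError(f"design is rank-deficient: term {term!r} is aliased")
        rank, col = new_rank, col + width
    return X, info


def _factor_levels(data: pd.DataFrame, var: str) -> list[str]:
    return sorted(data[var].astype(str).unique())


# ---------------------------------------------------------------------------
# results containers


@dataclass
class ModelFit:
    """Fitted permutation linear model (one row of statistics per term)."""

    formula: str
    terms: list[str]
    df: np.ndarray
    SS: np.ndarray
    R2: np.ndarray
    F: np.ndarray
    Z: np.ndarray
    P: np.ndarray
    df_residual: int
    SS_residual: float
    SS_total: float
    n_permutations: int
    seed: int | None
    mode: str                      # 'ols' | 'pgls'
    # private state for pairwise follow-ups
    _data: pd.DataFrame = field(repr=False, default=None)
    _Y: np.ndarray = field(repr=False, default=None)
    _transform: np.ndarray = field(repr=False, default=None)  # P matrix or None

    def anova_table(self) -> pd.DataFrame:
        rows = {
            t: {"Df": int(d), "SS": s, "R2": r2, "F": f, "Z": z, "P": p}
            for t, d, s, r2, f, z, p in zip(
                self.terms, self.df, self.SS, self.R2, self.F, self.Z, self.P)
        }
        rows["Residuals"] = {"Df": self.df_residual, "SS": self.SS_residual,
                             "R2": self.SS_residual / self.SS_total,
                             "F": np.nan, "Z": np.nan, "P": np.nan}
        rows["Total"] = {"Df": self.df_residual + int(self.df.sum()),
                         "SS": self.SS_total, "R2": 1.0,
                         "F": np.nan, "Z": np.nan, "P": np.nan}
        out = pd.DataFrame(rows).T
        out["Type"] = self.mode
        return out

    def term_index(self, term: str) -> int:
        if term not in self.terms:
            raise KeyError(f"term {term!r} not in model ({self.terms})")
        return self.terms.index(term)


@dataclass
class PairwiseResult:
    statistic: str
    groups: list[str]
    distance: pd.DataFrame      # observed statistic per pair
    P: pd.DataFrame
    Z: pd.DataFrame
    angle: pd.DataFrame | None = None      # slopes only, degrees
    angle_P: pd.DataFrame | None = None


@dataclass
class SignalResult:
    K: float
    P: float
    n_permutations: int


@dataclass
class DisparityResult:
    variances: pd.Series                    # Procrustes variance per group
    differences: pd.DataFrame               # pairwise |difference|
    P: pd.DataFrame
    excluded: list[str]


@dataclass
class RateResult:
    rates: pd.Series                        # sigma^2_mult per group
    ratio: float                            # max/min
    P: float
    Z: float
    n_simulations: int


# ---------------------------------------------------------------------------
# RRPP linear model


def _prep_pgls(data: pd.DataFrame, tree):
    C, _ = vcv_matrix(tree, list(data.index))
    return inv_sqrt_psd(C)


def rrpp_lm(
    Y: np.ndarray | pd.DataFrame,
    formula: str,
    data: pd.DataFrame,
    tree=None,
    n_perm: int = 999,
    seed: int | None = None,
) -> ModelFit:
    """Multivariate linear model with residual-randomization permutation.

    ``Y`` is an n x p response (rows in the order of ``data``); ``formula``
    is the right-hand side only (e.g. ``"size * diet"``). Passing a tree
    selects pgls mode: ``data.index`` must then hold species labels that
    match the tree's tips. P-values include the observed statistic in the
    reference set, so the smallest attainable P is 1/(n_perm + 1).
    """
    if isinstance(Y, (pd.DataFrame, pd.Series)):
        Y = np.asarray(Y, float)
    Y = np.atleast_2d(Y.astype(float))
    if Y.shape[0] == 1:
        Y = Y.T
    n = len(data)
    if Y.shape[0] != n:
        raise ValueError(f"Y has {Y.shape[0]} rows but data has {n}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    terms = parse_formula(formula)
    X, info = build_design(data, terms)

    mode = "pgls" if tree is not None else "ols"
    if tree is not None:
        T = _prep_pgls(data, tree)
        Yt, Xt = T @ Y, T @ X
    else:
        T = None
        Yt, Xt = Y, X

    # orthonormal bases of the nested sequence: intercept, +term1, +term1+term2...
    widths = [w for _, w in info]
    cuts = np.cumsum([1] + widths)
    Qs = []
    for c in cuts:
        Q, _ = np.linalg.qr(Xt[:, :c])
        Qs.append(Q)

    def rss(Q, M):
        return float((M ** 2).sum() - ((Q.T @ M) ** 2).sum())

    rss_seq = [rss(Q, Yt) for Q in Qs]          # index m: model with terms[:m]
    SS_total = rss_seq[0]
    SS_res = rss_seq[-1]
    df_res = n - cuts[-1]
    if df_res <= 0:
        raise DesignError("no residual degrees of freedom")
    SS = np.array([rss_seq[i] - rss_seq[i + 1] for i in range(len(terms))])
    df = np.array(widths)
    F_obs = (SS / df) / (SS_res / df_res)
    R2 = SS / SS_total if SS_total > 0 else np.zeros_like(SS)

    rng = np.random.default_rng(seed)
    perms = [np.arange(n)] + [rng.permutation(n) for _ in range(n_perm)]
    logF = np.empty((len(terms), len(perms)))
    for i in range(len(terms)):
        Q_red, Q_full = Qs[i], Qs[i + 1]
        fitted = Q_red @ (Q_red.T @ Yt)
        resid = Yt - fitted
        Q_last = Qs[-1]
        for j, perm in enumerate(perms):
            Ystar = fitted + resid[perm]
            r_red = rss(Q_red, Ystar)
            r_full = rss(Q_full, Ystar)
            r_last = rss(Q_last, Ystar)
            ss = max(r_red - r_full, 0.0)
            mse = max(r_last, 1e-300) / df_res
            logF[i, j] = np.log(max(ss / df[i] / mse, 1e-300))
    P = (logF >= logF[:, [0]] - 1e-12).mean(axis=1)
    mu, sd = logF.mean(axis=1), logF.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (logF[:, 0] - mu) / sd, 0.0)

    return ModelFit(
        formula=formula, terms=terms, df=df, SS=SS, R2=R2, F=F_obs, Z=Z, P=P,
        df_residual=df_res, SS_residual=SS_res, SS_total=SS_total,
        n_permutations=n_perm, seed=seed, mode=mode,
        _data=data, _Y=Y, _transform=T,
    )


# ---------------------------------------------------------------------------
# pairwise follow-ups


def _design_row(data, terms, grouping, level, mains_means):
    """One prediction row: grouping fixed to ``level``, everything else at its mean."""
    row = [1.0]
    for term in terms:
        parts = term.split(":")
        vals = []
        for p in parts:
            if p == grouping:
                levels = _factor_levels(data, grouping)
                vals.append(np.array([1.0 if lev == level else 0.0 for lev in levels[1:]]))
            else:
                vals.append(mains_means[p])
        block = vals[0]
        for v in vals[1:]:
            block = np.concatenate([block[i] * v for i in range(block.shape[0])])
        row.extend(block.tolist())
    return np.array(row)


def pairwise_groups(
    fit: ModelFit,
    grouping: str,
    statistic: str = "mean_distance",
    n_perm: int = 999,
    seed: int | None = None,
) -> PairwiseResult:
    """Pairwise group comparisons after an RRPP fit.

    ``mean_distance``: Euclidean distances between least-squares group mean
    shapes (other predictors held at their mean), tested by permuting
    residuals of the model without the grouping term (and its interactions).

    ``slope_angle_and_length``: for models with a grouping x continuous
    interaction, pairwise differences in slope-vector length and the angle
    between slope vectors, tested against the no-interaction null.
    """
    if grouping not in {p for t in fit.terms for p in t.split(":")}:
        raise KeyError(f"grouping {grouping!r} absent from model terms {fit.terms}")
    data, Y, T = fit._data, fit._Y, fit._transform
    n = len(data)
    terms = fit.terms
    levels = _factor_levels(data, grouping)
    rng = np.random.default_rng(seed)

    X_full, _ = build_design(data, terms)
    if statistic == "mean_distance":
        reduced_terms = [t for t in terms if grouping not in t.split(":")]
        stat_fn = _ls_mean_distances_factory(data, terms, grouping, levels)
    elif statistic == "slope_angle_and_length":
        inter = [t for t in terms if grouping in t.split(":") and len(t.split(":")) == 2]
        if not inter:
            raise DesignError(f"no {grouping} x continuous interaction in model")
        inter = inter[0]
        continuous = [p for p in inter.split(":") if p != grouping][0]
        reduced_terms = [t for t in terms if t != inter]
        stat_fn = _slopes_factory(data, terms, grouping, continuous, levels)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    if reduced_terms:
        X_red, _ = build_design(data, reduced_terms)
    else:
        X_red = np.ones((n, 1))
    if T is not None:
        Yt, Xf_t, Xr_t = T @ Y, T @ X_full, T @ X_red
    else:
        Yt, Xf_t, Xr_t = Y, X_full, X_red

    Qr, _ = np.linalg.qr(Xr_t)
    fitted = Qr @ (Qr.T @ Yt)
    resid = Yt - fitted
    pinv_full = np.linalg.pinv(Xf_t)

    perms = [np.arange(n)] + [rng.permutation(n) for _ in range(n_perm)]
    stats = []
    for perm in perms:
        beta = pinv_full @ (fitted + resid[perm])
        stats.append(stat_fn(beta))
    obs = stats[0]

    def frame(M):
        return pd.DataFrame(M, index=levels, columns=levels)

    if statistic == "mean_distance":
        D = np.stack([s for s in stats])        # (perm+1, L, L)
        P = (D >= D[0] - 1e-12).mean(axis=0)
        sd = D.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = np.where(sd > 0, (D[0] - D.mean(axis=0)) / sd, 0.0)
        np.fill_diagonal(P, 1.0)
        return PairwiseResult("mean_distance", levels, frame(D[0]), frame(P), frame(Z))
    else:
        lend = np.stack([s[0] for s in stats])
        ang = np.stack([s[1] for s in stats])
        P_len = (lend >= lend[0] - 1e-12).mean(axis=0)
        P_ang = (ang >= ang[0] - 1e-12).mean(axis=0)
        sd = lend.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = np.where(sd > 0, (lend[0] - lend.mean(axis=0)) / sd, 0.0)
        np.fill_diagonal(P_len, 1.0)
        np.fill_diagonal(P_ang, 1.0)
        return PairwiseResult("slope_angle_and_length", levels,
                              frame(lend[0]), frame(P_len), frame(Z),
                              angle=frame(ang[0]), angle_P=frame(P_ang))


def _ls_mean_distances_factory(data, terms, grouping, levels):
    mains_means = {}
    for term in terms:
        for p in term.split(":"):
            if p not in mains_means:
                enc, _ = _encode_main(data, p)
                mains_means[p] = enc.mean(axis=0)
    rows = np.stack([_design_row(data, terms, grouping, lev, mains_means) for lev in levels])

    def stat(beta):
        means = rows @ beta                     # (L, p)
        diff = means[:, None, :] - means[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=2))

    return stat


def _slopes_factory(data, terms, grouping, continuous, levels):
    # column layout bookkeeping: locate the continuous main effect and the
    # interaction block inside the full design
    col = 1
    slope_col = None
    inter_cols = None
    for term in terms:
        parts = term.split(":")
        enc_widths = []
        for p in parts:
            enc, w = _encode_main(data, p)
            enc_widths.append(w)
        width = int(np.prod(enc_widths))
        if term == continuous:
            slope_col = col
        if set(parts) == {grouping, continuous}:
            inter_cols = (col, col + width, parts)
        col += width

    def stat(beta):
        base = beta[slope_col]                  # (p,) slope of reference level
        lo, hi, parts = inter_cols
        block = beta[lo:hi]                     # (L-1, p) ordered by non-reference levels
        slopes = [base] + [base + block[i] for i in range(block.shape[0])]
        slopes = np.stack(slopes)               # (L, p)
        lengths = np.linalg.norm(slopes, axis=1)
        len_diff = np.abs(lengths[:, None] - lengths[None, :])
        unit = slopes / np.clip(lengths[:, None], 1e-300, None)
        cosang = np.clip(unit @ unit.T, -1.0, 1.0)
        angles = np.degrees(np.arccos(cosang))
        return len_diff, angles

    return stat


# ---------------------------------------------------------------------------
# phylogenetic signal


def physignal_K(
    Y: pd.DataFrame,
    tree,
    n_perm: int = 999,
    seed: int | None = None,
) -> SignalResult:
    """Multivariate Blomberg's K for species x p data on a dated tree.

    K is the ratio of mean-centered to phylogenetically corrected sums of
    squares, scaled by its Brownian-motion expectation; K near 1 is
    consistent with BM, K < 1 with homoplasy. Significance comes from
    permuting species across the tips.
    """
    C, order = vcv_matrix(tree, list(Y.index))
    Ymat = Y.to_numpy(dtype=float)
    if Ymat.ndim == 1:
        Ymat = Ymat[:, None]
    n = len(order)
    Cinv = np.linalg.inv(C)
    one = np.ones((n, 1))
    sum_cinv = float((one.T @ Cinv @ one).item())
    denom_expect = (np.trace(C) - n / sum_cinv) / (n - 1)

    def kstat(M):
        a = (one.T @ Cinv @ M) / sum_cinv
        R = M - a
        num = float((R ** 2).sum())
        den = float(np.einsum("ip,ij,jp->", R, Cinv, R))
        if den <= 0:
            return 0.0
        return (num / den) / denom_expect

    K_obs = kstat(Ymat)
    rng = np.random.default_rng(seed)
    ks = [K_obs]
    for _ in range(n_perm):
        ks.append(kstat(Ymat[rng.permutation(n)]))
    ks = np.array(ks)
    P = float((ks >= K_obs - 1e-12).mean())
    return SignalResult(K=float(K_obs), P=P, n_permutations=n_perm)


# ---------------------------------------------------------------------------
# disparity


def disparity_test(
    Y: np.ndarray | pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> DisparityResult:
    """Procrustes variance per group with pairwise permutation tests.

    Procrustes variance = mean squared Euclidean (shape-space) distance of
    group members from the group mean. Pairwise absolute differences are
    tested by permuting group labels; singleton groups are excluded with
    a warning.
    """
    from .geometry import ProcrustesAlignment

    if isinstance(Y, ProcrustesAlignment):
        Y = Y.flat()
    if isinstance(Y, pd.DataFrame):
        Y = Y.to_numpy(dtype=float)
    Y = Y.reshape(Y.shape[0], -1)
    groups = pd.Series(list(groups))
    counts = groups.value_counts()
    excluded = sorted(counts[counts < 2].index.tolist())
    if excluded:
        warnings.warn(f"excluding singleton groups: {excluded}", stacklevel=2)
    keep = ~groups.isin(excluded).to_numpy()
    Y = Y[keep]
    g = groups[keep].to_numpy()
    levels = sorted(set(g))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups with n >= 2")

    def pv(M, labels):
        out = {}
        for lev in levels:
            sub = M[labels == lev]
            out[lev] = float(((sub - sub.mean(axis=0)) ** 2).sum(axis=1).mean())
        return out

    obs = pv(Y, g)
    L = len(levels)
    obs_diff = np.abs(np.subtract.outer([obs[l] for l in levels], [obs[l] for l in levels]))
    rng = np.random.default_rng(seed)
    count = np.ones((L, L))
    for _ in range(n_perm):
        perm_pv = pv(Y, g[rng.permutation(len(g))])
        diff = np.abs(np.subtract.outer([perm_pv[l] for l in levels], [perm_pv[l] for l in levels]))
        count += diff >= obs_diff - 1e-15
    P = count / (n_perm + 1)
    np.fill_diagonal(P, 1.0)
    return DisparityResult(
        variances=pd.Series(obs),
        differences=pd.DataFrame(obs_diff, index=levels, columns=levels),
        P=pd.DataFrame(P, index=levels, columns=levels),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# evolutionary rates


def evol_rate_test(
    Y: pd.DataFrame,
    tree,
    grouping,
    n_sim: int = 999,
    seed: int | None = None,
) -> RateResult:
    """Per-group net multivariate Brownian rates and a max/min ratio test.

    sigma^2_mult for a group is the mean squared phylogenetically
    transformed tip deviation summed over dimensions. The null for the
    max/min ratio is parametric: BM with the common (pooled) rate is
    simulated on the tree, because permuting tips would destroy the
    tree-data covariance the statistic depends on.
    """
    C, order = vcv_matrix(tree, list(Y.index))
    Ymat = Y.to_numpy(dtype=float)
    if Ymat.ndim == 1:
        Ymat = Ymat[:, None]
    n, p = Ymat.shape
    g = pd.Series(grouping).reindex(order)
    if g.isna().any():
        raise KeyError(f"no group for species {sorted(g[g.isna()].index)}")
    levels = sorted(g.unique())
    small = [lev for lev in levels if (g == lev).sum() < 2]
    if small:
        raise ValueError(f"groups need >= 2 species: {small}")
    T = inv_sqrt_psd(C)
    a = phylo_gls_mean(C, Ymat)
    U = T @ (Ymat - a)
    sq = (U ** 2).sum(axis=1)

    def rates_of(sq_vec):
        return {lev: float(sq_vec[(g == lev).to_numpy()].mean()) for lev in levels}

    obs = rates_of(sq)
    vals = np.array([obs[lev] for lev in levels])
    ratio_obs = float(vals.max() / vals.min()) if len(levels) > 1 else 1.0
    sigma_common = float(sq.mean())

    rng = np.random.default_rng(seed)
    try:
        Lc = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        valsC, vecsC = np.linalg.eigh(C)
        Lc = vecsC * np.sqrt(np.clip(valsC, 0, None))
    log_ratios = [np.log(ratio_obs)]
    for _ in range(n_sim):
        Ysim = Lc @ rng.standard_normal((n, p)) * np.sqrt(sigma_common / p)
        asim = phylo_gls_mean(C, Ysim)
        sq_sim = ((T @ (Ysim - asim)) ** 2).sum(axis=1)
        r = rates_of(sq_sim)
        v = np.array([r[lev] for lev in levels])
        log_ratios.append(np.log(v.max() / v.min()))
    log_ratios = np.array(log_ratios)
    P = float((log_ratios >= log_ratios[0] - 1e-12).mean())
    sd = log_ratios.std(ddof=1)
    Z = float((log_ratios[0] - log_ratios.mean()) / sd) if sd > 0 else 0.0
    return RateResult(rates=pd.Series(obs), ratio=ratio_obs, P=P, Z=Z, n_simulations=n_sim)


# ---------------------------------------------------------------------------
# regression score


def regression_score(Y: np.ndarray | pd.DataFrame, x) -> np.ndarray:
    """Univariate shape summary maximally associated with a continuous x.

    Rows of (column-centered) Y are projected onto the normalized
    multivariate regression coefficient vector of Y on x.
    """
    if isinstance(Y, pd.DataFrame):
        Y = Y.to_numpy(dtype=float)
    Y = np.asarray(Y, float).reshape(len(x), -1)
    x = np.asarray(x, float)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise ValueError("x has zero variance")
    Yc = Y - Y.mean(axis=0)
    b = (Yc.T @ xc) / sxx
    nb = np.linalg.norm(b)
    if nb == 0:
        return np.zeros(Y.shape[0])
    return Yc @ (b / nb)
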