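"""Phylogenetic comparative statistics.

Brownian-motion (BM) covariance from a tree, Pagel's-lambda generalized
least squares (PGLS), simulation-based phylogenetic ANOVA with post hoc
pairwise tests and compact letter displays, phylogenetic PCA, and the
Spearman collinearity pruning applied before multivariate analyses.

Under BM with rate sigma^2, trait values at the tips are multivariate
normal with covariance sigma^2 * C, where C[i, j] is the root-to-MRCA path
length shared by tips i and j.  Pagel's lambda multiplies the off-diagonal
of C: lambda = 0 erases phylogenetic signal, lambda = 1 is full BM.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Tree -> covariance
# ---------------------------------------------------------------------------


def _has_branch_lengths(tree: dendropy.Tree) -> bool:
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            return False
    return True


def grafen_lengths(tree: dendropy.Tree) -> dendropy.Tree:
    """Assign branch lengths to a topology by Grafen's method.

    Node height above the tips = number of descendant tips - 1, normalized
    so the root-to-tip depth is 1; the tree becomes ultrametric in these
    units.  Used as a fallback for trees distributed as bare topologies.
    """
    tree = tree.clone(depth=1)
    heights = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            heights[node] = 0.0
        else:
            heights[node] = len(node.leaf_nodes()) - 1.0
    root_h = max(heights[tree.seed_node], 1.0)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            node.edge.length = 0.0
        else:
            node.edge.length = (heights[node.parent_node] - heights[node]) / root_h
    return tree


def bm_covariance(
    tree: dendropy.Tree, labels: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix of the tip states.

    ``C[i, j]`` is the depth (root-to-node path length) of the most recent
    common ancestor of tips i and j; the diagonal holds root-to-tip depths.
    Trees without branch lengths fall back to :func:`grafen_lengths`.

    Returns the matrix and the tip-label order used.
    """
    if not _has_branch_lengths(tree):
        tree = grafen_lengths(tree)
    leaves = [lf for lf in tree.leaf_node_iter()]
    tip_labels = [lf.taxon.label for lf in leaves]
    if labels is None:
        labels = tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    missing = set(labels) - set(tip_labels)
    if missing:
        raise KeyError(f"tips absent from tree: {sorted(missing)}")
    n = len(labels)
    C = np.zeros((n, n))

    depth = {tree.seed_node: 0.0}  # any stem below the root is ignored
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)

    tipsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            tips = [index[lab]] if lab in index else []
            tipsets[node] = tips
            if lab in index:
                C[index[lab], index[lab]] = depth[node]
            continue
        child_sets = [tipsets.pop(ch) for ch in node.child_nodes()]
        d = depth[node]
        for a, b in itertools.combinations(child_sets, 2):
            for i in a:
                for j in b:
                    C[i, j] = C[j, i] = d
        tipsets[node] = [i for s in child_sets for i in s]
    return C, list(labels)


def pagel_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale the off-diagonal of C by Pagel's lambda (diagonal unchanged)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    C = np.asarray(C, dtype=float)
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


def prune_tree(tree: dendropy.Tree, keep_labels) -> dendropy.Tree:
    """Clone of ``tree`` restricted to the given tip labels."""
    return tree.extract_tree_with_taxa_labels(labels=set(keep_labels))


# ---------------------------------------------------------------------------
# GLS machinery (with a fast path for ultrametric trees)
# ---------------------------------------------------------------------------


class _GLS:
    """Repeated GLS solves under C_lambda = lambda*C + (1-lambda)*diag(C).

    For ultrametric trees diag(C) = t*I, so C and C_lambda share
    eigenvectors: one symmetric eigendecomposition turns every likelihood
    evaluation into O(n p) work.  Non-ultrametric trees use a Cholesky
    factorization per evaluation.
    """

    def __init__(self, C: np.ndarray):
        self.C = np.asarray(C, dtype=float)
        d = np.diag(self.C)
        self.ultrametric = bool(np.ptp(d) <= 1e-8 * max(d.max(), 1e-300))
        if self.ultrametric:
            self.t = float(d[0])
            self.evals, self.Q = np.linalg.eigh(self.C)

    def whiten(self, lam: float, *arrays):
        """Return arrays premultiplied by C_lambda^{-1/2}, plus log|C_lambda|."""
        if self.ultrametric:
            dv = lam * (self.evals - self.t) + self.t
            if np.any(dv <= 0):
                return None, np.inf
            rot = [self.Q.T @ a for a in arrays]
            w = 1.0 / np.sqrt(dv)
            out = [r * (w[:, None] if r.ndim == 2 else w) for r in rot]
            return out, float(np.log(dv).sum())
        Cl = pagel_transform(self.C, lam)
        try:
            L = np.linalg.cholesky(Cl)
        except np.linalg.LinAlgError:
            return None, np.inf
        out = [np.linalg.solve(L, a) for a in arrays]
        return out, float(2.0 * np.log(np.diag(L)).sum())


def _gls_fit(g: _GLS, lam: float, y: np.ndarray, X: np.ndarray):
    """GLS estimates at fixed lambda.

    Returns (beta, sigma2_ML, loglik, XtWX_inv) or None when C_lambda is
    not positive definite.
    """
    out, logdet = g.whiten(lam, y, X)
    if out is None:
        return None
    yw, Xw = out
    n = len(y)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    r = yw - Xw @ beta
    sigma2 = float(r @ r) / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    ll = -0.5 * (n * (_LOG2PI + np.log(sigma2) + 1.0) + logdet)
    return beta, sigma2, ll, np.linalg.inv(XtX)


@dataclass(frozen=True)
class PGLSFit:
    """PGLS regression fit with jointly ML-estimated Pagel's lambda."""

    beta: np.ndarray
    se_beta: np.ndarray
    lambda_hat: float
    lambda_ci: tuple[float, float]
    residuals: np.ndarray
    loglik: float
    sigma2: float


def fit_pagel_lambda(
    y: np.ndarray,
    X: np.ndarray,
    C: np.ndarray,
    ci: bool = True,
) -> PGLSFit:
    """ML fit of a GLS regression with covariance sigma^2 * C_lambda.

    lambda is profiled over [0, 1] (boundary maxima allowed); the 95%
    confidence interval comes from the profile likelihood (drop of 1.92
    log-units), truncated at the boundaries.  Residuals are returned on the
    original scale, ``y - X beta``.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    if len(y) < X.shape[1] + 1:
        raise ValueError("too few observations for the design")
    g = _GLS(C)

    def nll(lam):
        fit = _gls_fit(g, lam, y, X)
        return np.inf if fit is None else -fit[2]

    res = optimize.minimize_scalar(
        nll, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-6}
    )
    cand = [(nll(0.0), 0.0), (nll(1.0), 1.0), (res.fun, float(res.x))]
    best_nll, lam_hat = min(cand, key=lambda t: t[0])
    beta, sigma2, ll, XtX_inv = _gls_fit(g, lam_hat, y, X)
    # sigma2 here is the ML variance of the whitened residuals; beta's
    # covariance is sigma2_unbiased * (X' C^-1 X)^-1
    n, p = X.shape
    s2_unbiased = sigma2 * n / max(n - p, 1)
    se = np.sqrt(np.diag(XtX_inv) * s2_unbiased)

    lo, hi = 0.0, 1.0
    if ci:
        thresh = ll - 1.92
        def drop(lam):
            return -nll(lam) - thresh
        if drop(0.0) < 0 and lam_hat > 0:
            lo = float(optimize.brentq(drop, 0.0, lam_hat, xtol=1e-5))
        if drop(1.0) < 0 and lam_hat < 1:
            hi = float(optimize.brentq(drop, lam_hat, 1.0, xtol=1e-5))
    return PGLSFit(
        beta=beta,
        se_beta=se,
        lambda_hat=lam_hat,
        lambda_ci=(lo, hi),
        residuals=y - X @ beta,
        loglik=ll,
        sigma2=sigma2,
    )


def pgls_residuals(
    trait: pd.Series,
    log_mass: pd.Series,
    tree: dendropy.Tree,
    ci: bool = False,
) -> tuple[pd.Series, PGLSFit]:
    """Residuals of ``trait ~ intercept + log_mass`` under PGLS.

    Species with a missing trait or mass are dropped and the tree pruned to
    the complete cases.  The residuals (original scale, indexed by species)
    carry the body-mass-corrected trait variation used by every downstream
    comparative test.
    """
    df = pd.DataFrame({"y": trait, "x": log_mass}).dropna()
    sub = prune_tree(tree, df.index)
    C, labels = bm_covariance(sub)
    df = df.loc[labels]
    X = np.column_stack([np.ones(len(df)), df["x"].to_numpy()])
    fit = fit_pagel_lambda(df["y"].to_numpy(), X, C, ci=ci)
    return pd.Series(fit.residuals, index=labels, name=trait.name), fit


# ---------------------------------------------------------------------------
# Phylogenetic ANOVA
# ---------------------------------------------------------------------------


def _anova_F(Y: np.ndarray, G: np.ndarray, counts: np.ndarray):
    """Vectorized one-way ANOVA over the columns of Y.

    Returns (F, group_means, MSW) for each column.
    """
    n, k = G.shape
    means = (G.T @ Y) / counts[:, None]
    grand = Y.mean(axis=0)
    ssb = (counts[:, None] * (means - grand) ** 2).sum(axis=0)
    sst = ((Y - grand) ** 2).sum(axis=0)
    ssw = np.maximum(sst - ssb, 0.0)
    msw = ssw / (n - k)
    F = (ssb / (k - 1)) / np.where(msw > 0, msw, np.nan)
    return F, means, msw


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def bonferroni_adjust(p, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: p * m capped at 1 (m defaults to len(p))."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    m = len(p) if m is None else m
    return np.minimum(p * m, 1.0)


def compact_letters(
    different: np.ndarray, group_names: list[str]
) -> dict[str, str]:
    """Compact letter display from a boolean 'significantly different'
    matrix: groups sharing a letter are not significantly different.

    Letters label the maximal cliques of the not-different graph, ordered
    by their first group.
    """
    k = len(group_names)
    Gn = nx.Graph()
    Gn.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if not different[i, j]:
                Gn.add_edge(i, j)
    cliques = sorted(
        (sorted(c) for c in nx.find_cliques(Gn)), key=lambda c: (c[0], c)
    )
    letters = {name: "" for name in group_names}
    for li, clique in enumerate(cliques):
        ch = chr(ord("a") + li)
        for i in clique:
            letters[group_names[i]] += ch
    return letters


@dataclass(frozen=True)
class PhyloANOVAResult:
    F_obs: float
    p_phylo: float
    r_squared: float
    df: tuple[int, int]
    group_means: pd.Series
    pairwise_p: pd.DataFrame
    letters: dict[str, str]
    nsim: int


def phylo_anova(
    values: pd.Series,
    groups: pd.Series,
    tree: dendropy.Tree,
    nsim: int = 1000,
    seed: int | None = None,
    p_adjust: str = "holm",
    alpha: float = 0.05,
) -> PhyloANOVAResult:
    """Simulation-based phylogenetic ANOVA with post hoc pairwise tests.

    The observed one-way F statistic is referred to a null distribution of
    F statistics computed from ``nsim`` Brownian-motion simulations on the
    tree (rate = REML estimate from the data), so the test is exact under
    BM evolution of the response regardless of how the groups cluster on
    the phylogeny.  Pairwise |t| statistics are referred to the same
    simulations and adjusted (Holm by default; 'bonferroni' and 'none'
    also supported); the compact letter display reflects the adjusted
    pairwise significance at ``alpha``.
    """
    df = pd.DataFrame({"y": values, "g": groups}).dropna()
    if df["g"].nunique() < 2:
        raise ValueError("phylo_anova needs at least two non-empty groups")
    sub = prune_tree(tree, df.index)
    C, labels = bm_covariance(sub)
    df = df.loc[labels]
    y = df["y"].to_numpy(dtype=float)
    n = len(y)
    group_names = sorted(df["g"].unique(), key=str)
    gidx = df["g"].map({g: i for i, g in enumerate(group_names)}).to_numpy()
    k = len(group_names)
    G = np.zeros((n, k))
    G[np.arange(n), gidx] = 1.0
    counts = G.sum(axis=0)

    F_obs, means_obs, msw_obs = _anova_F(y[:, None], G, counts)
    F_obs = float(F_obs[0])
    if not np.isfinite(F_obs):
        raise ValueError("degenerate residual variance in phylo_anova")

    # BM rate: REML estimate of the residual variance about the GLS mean
    Cinv_y = np.linalg.solve(C, y)
    Cinv_1 = np.linalg.solve(C, np.ones(n))
    mu = float(Cinv_y.sum() / Cinv_1.sum())
    r = y - mu
    rate = float(r @ np.linalg.solve(C, r)) / (n - 1)

    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(C + 1e-12 * np.trace(C) / n * np.eye(n))
    Y = L @ rng.standard_normal((n, nsim)) * np.sqrt(rate)
    F_sim, means_sim, msw_sim = _anova_F(Y, G, counts)

    p_phylo = float((1 + np.sum(F_sim >= F_obs)) / (nsim + 1))

    pairs = list(itertools.combinations(range(k), 2))
    inv_n = 1.0 / counts
    t_obs = np.empty(len(pairs))
    p_pair = np.empty(len(pairs))
    for idx, (i, j) in enumerate(pairs):
        denom_obs = np.sqrt(msw_obs[0] * (inv_n[i] + inv_n[j]))
        t_obs[idx] = abs(means_obs[i, 0] - means_obs[j, 0]) / denom_obs
        t_sim = np.abs(means_sim[i] - means_sim[j]) / np.sqrt(
            msw_sim * (inv_n[i] + inv_n[j])
        )
        p_pair[idx] = (1 + np.sum(t_sim >= t_obs[idx])) / (nsim + 1)
    if p_adjust == "holm":
        p_adj = holm_adjust(p_pair)
    elif p_adjust == "bonferroni":
        p_adj = bonferroni_adjust(p_pair)
    elif p_adjust == "none":
        p_adj = p_pair.copy()
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")

    P = pd.DataFrame(np.ones((k, k)), index=group_names, columns=group_names)
    different = np.zeros((k, k), dtype=bool)
    for (i, j), padj in zip(pairs, p_adj):
        P.iloc[i, j] = P.iloc[j, i] = padj
        different[i, j] = different[j, i] = padj < alpha
    letters = compact_letters(different, list(map(str, group_names)))

    ssb_frac = float(
        (counts * (means_obs[:, 0] - y.mean()) ** 2).sum()
        / ((y - y.mean()) ** 2).sum()
    )
    return PhyloANOVAResult(
        F_obs=F_obs,
        p_phylo=p_phylo,
        r_squared=ssb_frac,
        df=(k - 1, n - k),
        group_means=pd.Series(means_obs[:, 0], index=group_names),
        pairwise_p=P,
        letters=letters,
        nsim=nsim,
    )


# ---------------------------------------------------------------------------
# Phylogenetic PCA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PPCAResult:
    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    scores: pd.DataFrame
    pct_variance: np.ndarray
    lambda_hat: float
    retained_axes: int


def ppca(X: pd.DataFrame, tree: dendropy.Tree) -> PPCAResult:
    """Phylogenetic principal component analysis.

    The trait matrix (complete cases, columns typically standardized to
    mean 0 / variance 1 beforehand) is centred on the phylogenetic GLS
    mean ``a = (1'C^-1 1)^-1 1'C^-1 X`` and decomposed through the
    evolutionary covariance ``R = (X - 1a)' C^-1 (X - 1a) / (n - 1)``, with
    C evaluated at the jointly ML-estimated Pagel's lambda of the
    multivariate Brownian model.  Axes with eigenvalue > 1 are retained
    (Kaiser's criterion; meaningful when columns have unit variance).
    """
    if X.isna().any().any():
        raise ValueError("ppca requires a complete (imputed) trait matrix")
    sub = prune_tree(tree, X.index)
    C, labels = bm_covariance(sub)
    Xv = X.loc[labels].to_numpy(dtype=float)
    n, p = Xv.shape
    if n <= p:
        raise ValueError("need more species than traits")
    ones = np.ones((n, 1))
    g = _GLS(C)

    def nll(lam):
        out, logdet = g.whiten(lam, Xv, ones)
        if out is None:
            return np.inf
        Xw, ow = out
        a = np.linalg.lstsq(ow, Xw, rcond=None)[0]
        E = Xw - ow @ a
        R = (E.T @ E) / n
        sign, logdetR = np.linalg.slogdet(R)
        if sign <= 0:
            return np.inf
        return 0.5 * (n * p * _LOG2PI + p * logdet + n * logdetR + n * p)

    res = optimize.minimize_scalar(
        nll, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-6}
    )
    cand = [(nll(0.0), 0.0), (nll(1.0), 1.0), (res.fun, float(res.x))]
    _, lam_hat = min(cand, key=lambda t: t[0])

    Cl = pagel_transform(C, lam_hat)
    Cinv_1 = np.linalg.solve(Cl, np.ones(n))
    a = (Cinv_1 @ Xv) / Cinv_1.sum()
    E = Xv - a
    R = E.T @ np.linalg.solve(Cl, E) / (n - 1)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(p):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = E @ evecs
    pct = 100.0 * evals / evals.sum()
    axes = [f"PC{i + 1}" for i in range(p)]
    return PPCAResult(
        loadings=pd.DataFrame(evecs, index=X.columns, columns=axes),
        eigenvalues=evals,
        scores=pd.DataFrame(scores, index=labels, columns=axes),
        pct_variance=pct,
        lambda_hat=lam_hat,
        retained_axes=int(np.sum(evals > 1.0)),
    )


# ---------------------------------------------------------------------------
# Collinearity pruning
# ---------------------------------------------------------------------------


def spearman_prune(
    trait_table: pd.DataFrame,
    threshold: float = 0.70,
    canonical_order: list[str] | None = None,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Drop one trait of every pair with |Spearman rho| strictly above the
    threshold.

    Pairs are processed from the strongest correlation down; within a pair
    the trait with lower missingness is kept (ties broken by the canonical
    order, which defaults to the table's column order).  Returns the kept
    trait names and the dropped pairs with their correlations.
    """
    cols = list(trait_table.columns)
    order = canonical_order or cols
    rank = {c: order.index(c) if c in order else len(order) for c in cols}
    rho = trait_table.corr(method="spearman")
    miss = trait_table.isna().mean()

    pairs = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = rho.loc[a, b]
            if pd.notna(r) and abs(r) > threshold:
                pairs.append((a, b, float(r)))
    pairs.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))

    dropped: set[str] = set()
    log = []
    for a, b, r in pairs:
        if a in dropped or b in dropped:
            continue
        if (miss[a], rank[a]) <= (miss[b], rank[b]):
            keep, drop = a, b
        else:
            keep, drop = b, a
        dropped.add(drop)
        log.append((keep, drop, r))
    kept = [c for c in cols if c not in dropped]
    return kept, log
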