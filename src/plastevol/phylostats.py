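"""Phylogenetically corrected group comparisons.

Closely related species are not independent samples: under a Brownian-motion
model of trait change the expected covariance of two tips equals the shared
root-to-divergence path length.  All tests here are generalized least squares
with that covariance (the "phylogenetic t-test" is a GLS on a 0/1 dummy
regressor), except the phylogenetic ANOVA, whose null F distribution is
generated by Brownian simulation on the tree with simulation-based post-hoc
pairwise tests (Holm-corrected by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .molevol import BranchTree

Phylogeny = BranchTree  # rooted, branch lengths in time-like units


def brownian_vcv(tree: BranchTree) -> tuple[np.ndarray, list[str]]:
    """Brownian covariance: C[i,j] = shared root-to-MRCA path length.

    Returns the matrix and the tip labels in its row order.  Zero-depth
    trees are rejected; zero off-diagonal singularities from polytomies
    resolved with zero-length branches are handled by callers via the
    small-ridge option of :func:`gls_fit`.
    """
    tips = tree.tips
    labels = [tree.labels[v] for v in tips]
    depth = np.zeros(tree.n_nodes)
    # preorder: parent before child holds for postorder reversed
    for v in reversed(tree.postorder):
        p = tree.parent[v]
        depth[v] = (depth[p] if p >= 0 else 0.0) + (tree.lengths[v] if p >= 0 else 0.0)
    # ancestor sets via path to root
    paths = []
    for v in tips:
        path = []
        u = v
        while u >= 0:
            path.append(u)
            u = tree.parent[u]
        paths.append(set(path))
    n = len(tips)
    C = np.zeros((n, n))
    for i in range(n):
        C[i, i] = depth[tips[i]]
        for j in range(i + 1, n):
            shared = paths[i] & paths[j]
            mrca_depth = max(depth[u] for u in shared)
            C[i, j] = C[j, i] = mrca_depth
    if np.max(np.diag(C)) <= 0:
        raise ValueError("zero-depth tree: Brownian covariance is singular")
    return C, labels


@dataclass(frozen=True)
class ComparativeTestResult:
    method: str  # phylo_t | pgls | phylo_anova
    statistic: float
    df: float
    p: float
    estimates: Mapping[str, float]
    posthoc: "pandas.DataFrame | None" = None


def gls_fit(X: np.ndarray, y: np.ndarray, C: np.ndarray, ridge: float = 0.0):
    """GLS estimates for y = X beta + e, e ~ N(0, sigma^2 C).

    Returns (beta, se, sigma2_hat, df_resid).  ``ridge`` adds
    ridge * mean(diag(C)) to the diagonal (used for zero-length-branch
    degeneracies).
    """
    n, p = X.shape
    if ridge:
        C = C + ridge * float(np.mean(np.diag(C))) * np.eye(n)
    L = np.linalg.cholesky(C)
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    return beta, se, sigma2, df


def _align(y: Mapping[str, float] | Sequence[float], labels: Sequence[str]) -> np.ndarray:
    if isinstance(y, Mapping):
        missing = [t for t in labels if t not in y]
        if missing:
            raise KeyError(f"trait values missing for taxa: {missing}")
        arr = np.array([float(y[t]) for t in labels])
    else:
        arr = np.asarray(y, dtype=float)
        if len(arr) != len(labels):
            raise ValueError("trait vector length does not match tip count")
    if not np.isfinite(arr).all():
        raise ValueError("trait values must be finite")
    return arr


def phylo_ttest(
    y: Mapping[str, float] | Sequence[float],
    group01: Mapping[str, int] | Sequence[int],
    tree: BranchTree,
    ridge: float = 1e-8,
) -> ComparativeTestResult:
    """Two-group comparison as GLS with a dummy-coded regressor.

    ``group01`` assigns 0/1 per taxon; the reported statistic is the t of
    the group coefficient with n - 2 degrees of freedom, two-sided.
    """
    C, labels = brownian_vcv(tree)
    yv = _align(y, labels)
    g = _align(group01, labels)
    if set(np.unique(g)) - {0.0, 1.0}:
        raise ValueError("group01 must be coded 0/1")
    if len(np.unique(g)) < 2:
        raise ValueError("both groups must be nonempty")
    X = np.column_stack([np.ones_like(yv), g])
    beta, se, sigma2, df = gls_fit(X, yv, C, ridge=ridge)
    if se[1] == 0:
        t = 0.0
        p = 1.0
    else:
        t = float(beta[1] / se[1])
        p = float(2 * stats.t.sf(abs(t), df))
    return ComparativeTestResult(
        method="phylo_t",
        statistic=t,
        df=df,
        p=p,
        estimates={"mean_group0": float(beta[0]), "difference": float(beta[1]), "sigma2": sigma2},
    )


def pgls(
    y: Mapping[str, float] | Sequence[float],
    x: Mapping[str, float] | Sequence[float],
    tree: BranchTree,
    ridge: float = 1e-8,
) -> ComparativeTestResult:
    """Phylogenetic least-squares regression of y on a continuous x."""
    C, labels = brownian_vcv(tree)
    yv = _align(y, labels)
    xv = _align(x, labels)
    if len(labels) < 3:
        raise ValueError("PGLS requires at least 3 tips")
    if np.ptp(xv) == 0:
        raise ValueError("constant predictor")
    X = np.column_stack([np.ones_like(yv), xv])
    beta, se, sigma2, df = gls_fit(X, yv, C, ridge=ridge)
    t = float(beta[1] / se[1]) if se[1] > 0 else float("inf") * np.sign(beta[1])
    p = float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return ComparativeTestResult(
        method="pgls",
        statistic=t,
        df=df,
        p=p,
        estimates={"intercept": float(beta[0]), "slope": float(beta[1]), "sigma2": sigma2},
    )


def _anova_f(yv: np.ndarray, codes: np.ndarray, k: int) -> float:
    grand = yv.mean()
    ssb = sum(
        len(yv[codes == g]) * (yv[codes == g].mean() - grand) ** 2 for g in range(k)
    )
    ssw = sum(((yv[codes == g] - yv[codes == g].mean()) ** 2).sum() for g in range(k))
    dfb, dfw = k - 1, len(yv) - k
    if ssw <= 0:
        raise ValueError("zero within-group variance: F undefined")
    return float((ssb / dfb) / (ssw / dfw))


def _pairwise_t(yv: np.ndarray, codes: np.ndarray, k: int) -> np.ndarray:
    """Post-hoc pairwise t statistics with the pooled ANOVA error term."""
    n = len(yv)
    mse = (
        sum(((yv[codes == g] - yv[codes == g].mean()) ** 2).sum() for g in range(k))
        / (n - k)
    )
    T = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            na, nb = (codes == a).sum(), (codes == b).sum()
            se = np.sqrt(mse * (1 / na + 1 / nb))
            T[a, b] = T[b, a] = (yv[codes == a].mean() - yv[codes == b].mean()) / se
    return T


def holm(pvals: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (monotone, bounded by 1)."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = (m - rank) * pvals[idx]
        running = max(running, val)
        adj[idx] = min(1.0, running)
    return adj.tolist()


def phylo_anova(
    y: Mapping[str, float] | Sequence[float],
    groups: Mapping[str, str] | Sequence[str],
    tree: BranchTree,
    n_sim: int = 1000,
    seed: int = 0,
    correction: str = "holm",
) -> ComparativeTestResult:
    """Simulation-based phylogenetic ANOVA with post-hoc pairwise tests.

    The F statistic is the ordinary one-way ANOVA F on the observed values;
    its null distribution comes from ``n_sim`` Brownian simulations on the
    tree (the Brownian rate does not affect F, which is scale-free).
    Post-hoc pairwise t statistics use the same simulations; pairwise
    p-values are Holm-corrected by default (``bonferroni`` and ``bh``
    also available).
    """
    if n_sim < 500:
        raise ValueError("n_sim must be >= 500 for a stable simulation null")
    import pandas as pd

    C, labels = brownian_vcv(tree)
    yv = _align(y, labels)
    if isinstance(groups, Mapping):
        glist = [groups[t] for t in labels]
    else:
        glist = list(groups)
    names = sorted(set(glist))
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 groups")
    codes = np.array([names.index(g) for g in glist])

    F_obs = _anova_f(yv, codes, k)
    T_obs = _pairwise_t(yv, codes, k)

    rng = np.random.default_rng(seed)
    Lchol = np.linalg.cholesky(C + 1e-10 * float(np.mean(np.diag(C))) * np.eye(len(yv)))
    Z = rng.standard_normal((n_sim, len(yv)))
    sims = Z @ Lchol.T

    F_null = np.empty(n_sim)
    T_null = np.empty((n_sim, k, k))
    for s in range(n_sim):
        F_null[s] = _anova_f(sims[s], codes, k)
        T_null[s] = _pairwise_t(sims[s], codes, k)
    p_F = float((np.sum(F_null >= F_obs) + 1) / (n_sim + 1))

    raw = {}
    for a in range(k):
        for b in range(a + 1, k):
            exceed = np.sum(np.abs(T_null[:, a, b]) >= abs(T_obs[a, b]))
            raw[(a, b)] = float((exceed + 1) / (n_sim + 1))
    keys = sorted(raw)
    if correction == "holm":
        adj = holm([raw[kk] for kk in keys])
    elif correction == "bonferroni":
        adj = [min(1.0, raw[kk] * len(keys)) for kk in keys]
    elif correction == "bh":
        from statistics import NormalDist  # noqa: F401 - no scipy dependency needed

        m = len(keys)
        order = np.argsort([raw[kk] for kk in keys])
        vals = np.array([raw[kk] for kk in keys])
        adj_arr = np.empty(m)
        prev = 1.0
        for rank in range(m - 1, -1, -1):
            idx = order[rank]
            prev = min(prev, vals[idx] * m / (rank + 1))
            adj_arr[idx] = prev
        adj = adj_arr.tolist()
    else:
        raise ValueError(f"unknown correction {correction!r}")

    P = np.full((k, k), np.nan)
    np.fill_diagonal(P, 1.0)
    for (a, b), pv in zip(keys, adj):
        P[a, b] = P[b, a] = pv
    posthoc = pd.DataFrame(P, index=names, columns=names)

    means = {f"mean_{names[g]}": float(yv[codes == g].mean()) for g in range(k)}
    return ComparativeTestResult(
        method="phylo_anova",
        statistic=F_obs,
        df=float(k - 1),
        p=p_F,
        estimates=means,
        posthoc=posthoc,
    )
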