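"""Brownian-motion phylogenetic comparative statistics.

Under Brownian motion (BM) with rate sigma^2, trait values at the tips of a
rooted tree are jointly Gaussian with covariance sigma^2 * C, where
C[i, j] is the shared root-to-MRCA path length of tips i and j.  Everything
in this module is built on that covariance: generalized least squares
regression (PGLS), Blomberg's K and its multivariate extension Kmult with
permutation tests, maximum-likelihood ancestral states, and BM simulation.

Species order is fixed to sorted tip labels everywhere, so matrices and
data vectors align by construction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.stats

from .io_formats import Phylogeny


@dataclass
class BMCovariance:
    """Tip covariance structure induced by Brownian motion on a tree."""

    species: list[str]
    matrix: np.ndarray  # (n, n), C[i,j] = depth of MRCA(i, j)

    def submatrix(self, species: list[str]) -> "BMCovariance":
        idx = [self.species.index(s) for s in species]
        return BMCovariance(list(species), self.matrix[np.ix_(idx, idx)])


@dataclass
class PGLSFit:
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p_t: np.ndarray
    fstat: float
    p_f: float
    r2: float
    n: int
    predictors: list[str]
    residuals: np.ndarray  # whitened residuals


@dataclass
class SignalResult:
    statistic: float
    p: float
    n_perm: int
    seed: int
    name: str = "K"


def _node_depths(phy: Phylogeny) -> dict:
    depths = {}
    for node in phy.tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + node.edge.length
    return depths


def bm_covariance(phy: Phylogeny) -> BMCovariance:
    """C[i, j] = root-to-MRCA path length; diagonal = tip depths."""
    depths = _node_depths(phy)
    leaves = {leaf.taxon.label: leaf for leaf in phy.tree.leaf_node_iter()}
    species = phy.tip_labels
    n = len(species)
    # ancestor chains (root first) for MRCA depth lookup
    chains = {}
    for lab, leaf in leaves.items():
        chain = []
        node = leaf
        while node is not None:
            chain.append(node)
            node = node.parent_node
        chains[lab] = chain[::-1]
    C = np.zeros((n, n))
    for i, a in enumerate(species):
        C[i, i] = depths[leaves[a]]
        for j in range(i + 1, n):
            b = species[j]
            ca, cb = chains[a], chains[b]
            mrca = None
            for u, v in zip(ca, cb):
                if u is v:
                    mrca = u
                else:
                    break
            C[i, j] = C[j, i] = depths[mrca]
    return BMCovariance(list(species), C)


def simulate_bm(
    phy: Phylogeny,
    rate: float = 1.0,
    root_state: float = 0.0,
    seed: int = 0,
    n_reps: int = 1,
) -> np.ndarray:
    """Simulate BM tip values; returns (n_tips, n_reps) in sorted-label order.

    Increments along each branch are independent N(0, rate * length), drawn
    in a deterministic preorder traversal so a given seed always yields the
    same matrix.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    values: dict = {}
    out = {}
    for node in phy.tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = np.full(n_reps, float(root_state))
        else:
            incr = rng.normal(0.0, math.sqrt(rate * node.edge.length), size=n_reps)
            values[node] = values[node.parent_node] + incr
        if node.is_leaf():
            out[node.taxon.label] = values[node]
    return np.vstack([out[s] for s in phy.tip_labels])


def gls_mean(x: np.ndarray, Cinv: np.ndarray) -> float:
    """Phylogenetic (GLS) mean a = (1' C^-1 1)^-1 1' C^-1 x."""
    one = np.ones(len(x))
    return float(one @ Cinv @ x / (one @ Cinv @ one))


def pgls_fit(
    y: np.ndarray,
    X: np.ndarray,
    C: np.ndarray,
    predictors: list[str] | None = None,
) -> PGLSFit:
    """GLS regression with BM error covariance C (intercept added).

    beta = (X' C^-1 X)^-1 X' C^-1 y, computed by Cholesky whitening.  R^2 is
    defined against the GLS (phylogenetic) mean in whitened space, which
    reduces to the classical R^2 on a star tree.  The F statistic tests all
    non-intercept terms jointly; t statistics are per-coefficient.
    """
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y):
        X = X.T
    n = len(y)
    names = ["intercept"] + (predictors or [f"x{i}" for i in range(X.shape[1])])
    Xd = np.column_stack([np.ones(n), X])
    p = Xd.shape[1] - 1
    if n - p - 1 <= 0:
        raise ValueError(f"insufficient df: n={n}, predictors={p}")
    L = sla.cholesky(C, lower=True)
    yw = sla.solve_triangular(L, y, lower=True)
    Xw = sla.solve_triangular(L, Xd, lower=True)
    XtX = Xw.T @ Xw
    cond = np.linalg.cond(XtX)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"singular design (predictors {names[1:]})")
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    onew = sla.solve_triangular(L, np.ones(n), lower=True)
    a = float(onew @ yw / (onew @ onew))
    tss = float((yw - a * onew) @ (yw - a * onew))
    df_resid = n - p - 1
    sigma2 = rss / df_resid
    cov_beta = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    tstat = beta / se
    p_t = 2.0 * scipy.stats.t.sf(np.abs(tstat), df_resid)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if p > 0:
        f = ((tss - rss) / p) / (rss / df_resid)
        p_f = float(scipy.stats.f.sf(f, p, df_resid))
    else:
        f, p_f = float("nan"), float("nan")
    return PGLSFit(beta, se, tstat, p_t, float(f), p_f, float(r2), n, names, resid)


def _k_numerator_denominator(X: np.ndarray, Cinv: np.ndarray) -> tuple[float, float]:
    one = np.ones(X.shape[0])
    denom_a = one @ Cinv @ one
    a = (one @ Cinv @ X) / denom_a  # per-column GLS mean
    D = X - np.outer(one, a)
    num = float(np.sum(D * D))
    den = float(np.sum(D * (Cinv @ D)))
    return num, den


def _k_statistic(X: np.ndarray, C: np.ndarray, Cinv: np.ndarray) -> float:
    n = X.shape[0]
    one = np.ones(n)
    num, den = _k_numerator_denominator(X, Cinv)
    expected = (np.trace(C) - n / (one @ Cinv @ one)) / (n - 1)
    return (num / den) / expected


def k_statistic(x: np.ndarray, phy: Phylogeny) -> float:
    """Blomberg's K (or Kmult for multi-column input) without a
    permutation test; useful for replicate averages."""
    X = np.atleast_2d(np.asarray(x, float))
    if X.shape[0] != phy.n_tips and X.shape[1] == phy.n_tips:
        X = X.T
    C = bm_covariance(phy).matrix
    return _k_statistic(X, C, np.linalg.inv(C))


def blomberg_k(
    x: np.ndarray, phy: Phylogeny, n_perm: int = 999, seed: int = 0
) -> SignalResult:
    """Blomberg's K with a tip-shuffling permutation test.

    K = [(x-a)'(x-a) / (x-a)'C^-1(x-a)] / [(tr C - n/(1'C^-1 1)) / (n-1)],
    a the GLS mean.  K = 1 is the BM expectation; the permutation p-value
    uses the (1 + exceedances)/(n_perm + 1) correction.
    """
    X = np.asarray(x, float).reshape(-1, 1)
    return kmult(X, phy, n_perm=n_perm, seed=seed, name="K")


def kmult(
    X: np.ndarray,
    phy: Phylogeny,
    n_perm: int = 999,
    seed: int = 0,
    name: str = "Kmult",
) -> SignalResult:
    """Multivariate K: squared norms replace squares; one column == K."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != phy.n_tips and X.shape[1] == phy.n_tips:
        X = X.T
    if X.shape[0] != phy.n_tips:
        raise ValueError("data rows must match tree tips")
    C = bm_covariance(phy).matrix
    Cinv = np.linalg.inv(C)
    k_obs = _k_statistic(X, C, Cinv)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _k_statistic(X[perm], C, Cinv) >= k_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return SignalResult(float(k_obs), float(p), n_perm, seed, name)


def ancestral_states(
    x: np.ndarray, phy: Phylogeny
) -> tuple[dict[int, float], dict[int, float], Phylogeny]:
    """ML ancestral states under BM with prediction variances.

    The joint distribution of tip and internal-node values under BM is
    Gaussian with covariance built from shared path lengths; estimates are
    the conditional expectations given the tips, with the GLS mean plugged
    in for the root state.  Returns ({node_id: estimate},
    {node_id: variance}, phylogeny) where node_id is the preorder index of
    each internal node (0 = root); the root estimate equals the GLS mean.

    Variances include the conditional variance plus the propagated
    uncertainty of the estimated root state; they are scaled by the ML
    Brownian rate estimated from the tip data.
    """
    x = np.asarray(x, float).ravel()
    species = phy.tip_labels
    n = len(species)
    if len(x) != n:
        raise ValueError("trait length must match tip count")
    depths = _node_depths(phy)
    internal = [nd for nd in phy.tree.preorder_node_iter() if not nd.is_leaf()]
    leaves = {leaf.taxon.label: leaf for leaf in phy.tree.leaf_node_iter()}

    def chain(node):
        c = []
        while node is not None:
            c.append(node)
            node = node.parent_node
        return c[::-1]

    chains = {id(nd): chain(nd) for nd in phy.tree.preorder_node_iter()}

    def mrca_depth(a, b):
        m = None
        for u, v in zip(chains[id(a)], chains[id(b)]):
            if u is v:
                m = u
            else:
                break
        return depths[m]

    Ctt = np.array(
        [[mrca_depth(leaves[a], leaves[b]) for b in species] for a in species]
    )
    Cit = np.array(
        [[mrca_depth(nd, leaves[b]) for b in species] for nd in internal]
    )
    Cii = np.array([depths[nd] for nd in internal])
    Cinv = np.linalg.inv(Ctt)
    one = np.ones(n)
    denom = one @ Cinv @ one
    a_hat = float(one @ Cinv @ x / denom)
    w = Cit @ Cinv  # (n_internal, n_tips) conditioning weights
    est = a_hat + w @ (x - a_hat * one)
    # ML BM rate from tips (GLS residual quadratic form / n)
    resid = x - a_hat * one
    rate = float(resid @ Cinv @ resid) / n
    cond_var = Cii - np.sum(w * Cit, axis=1)
    mean_var = (1.0 - w @ one) ** 2 / denom
    var = rate * np.clip(cond_var + mean_var, 0.0, None)
    estimates = {i: float(v) for i, v in enumerate(est)}
    variances = {i: float(v) for i, v in enumerate(var)}
    return estimates, variances, phy


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Mann-Whitney U with exact enumeration for n_a + n_b <= 12.

    The exact branch enumerates all C(n_a+n_b, n_a) group labelings of the
    pooled sample (ties handled by midranks) and returns the two-sided
    p-value 2*min(P(U <= u), P(U >= u)) capped at 1; larger samples use the
    tie-corrected normal approximation.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    u_obs = float(np.sum(ranks[:na]) - na * (na + 1) / 2)
    if na + nb <= 12:
        idx = range(na + nb)
        lo = hi = 0
        total = 0
        for comb in itertools.combinations(idx, na):
            u = float(np.sum(ranks[list(comb)]) - na * (na + 1) / 2)
            total += 1
            if u <= u_obs + 1e-12:
                lo += 1
            if u >= u_obs - 1e-12:
                hi += 1
        p = min(1.0, 2.0 * min(lo, hi) / total)
        return u_obs, p
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
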