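"""Procrustes superimposition and (phylogenetic) principal component
analysis of landmark configurations.

Generalized Procrustes Analysis removes location (centering), scale
(division by centroid size) and orientation (optimal rotation, reflections
excluded) from each configuration, leaving Procrustes shape coordinates.
Shape variation across species is then summarised by PCA of the
covariance of the vectorized coordinates, or by phylogenetic PCA, which
uses the evolutionary covariance R = (X - 1 a')' C^-1 (X - 1 a') / (n - 1)
with a the GLS phylogenetic mean and C the Brownian-motion tip covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Phylogeny
from .phylo import bm_covariance


@dataclass
class ProcrustesResult:
    aligned: np.ndarray          # (k, p, 3) unit-size, origin-centered
    consensus: np.ndarray        # (p, 3)
    centroid_sizes: np.ndarray   # (k,) sizes before scaling
    iterations: int
    converged: bool


@dataclass
class PCAResult:
    mean: np.ndarray             # (3p,)
    eigenvalues: np.ndarray      # descending
    loadings: np.ndarray         # (3p, k) orthonormal columns
    scores: np.ndarray           # (n, k)
    variance_fractions: np.ndarray
    labels: list[str]
    kind: str = "pca"            # "pca" or "ppca"


def _center_scale(config: np.ndarray) -> tuple[np.ndarray, float]:
    c = config - config.mean(axis=0)
    cs = float(np.sqrt(np.sum(c * c)))
    if cs == 0.0:
        raise ValueError("degenerate configuration (all points coincident)")
    return c / cs, cs


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (no reflection) minimising ||source @ R - target||_F."""
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.ones(source.shape[1])
    s[-1] = d
    return (u * s) @ vt


def procrustes_align(
    configs: np.ndarray, tol: float = 1e-10, max_iter: int = 100
) -> ProcrustesResult:
    """Iterative GPA: center, scale to unit centroid size, rotate each
    configuration to the running consensus until the consensus moves less
    than ``tol`` (RMS) or ``max_iter`` is reached."""
    configs = np.asarray(configs, float)
    if configs.ndim != 3 or configs.shape[0] < 2:
        raise ValueError("need >= 2 configurations of equal landmark count")
    k = configs.shape[0]
    scaled = []
    sizes = []
    for i in range(k):
        c, cs = _center_scale(configs[i])
        scaled.append(c)
        sizes.append(cs)
    aligned = np.array(scaled)
    consensus = aligned[0].copy()
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        for i in range(k):
            aligned[i] = aligned[i] @ optimal_rotation(aligned[i], consensus)
        new_consensus = aligned.mean(axis=0)
        new_consensus /= np.sqrt(np.sum(new_consensus**2))
        delta = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    return ProcrustesResult(aligned, aligned.mean(axis=0), np.array(sizes),
                            iterations, converged)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations."""
    ca, _ = _center_scale(np.asarray(a, float))
    cb, _ = _center_scale(np.asarray(b, float))
    ca = ca @ optimal_rotation(ca, cb)
    return float(np.sqrt(np.sum((ca - cb) ** 2)))


def species_consensus(
    aligned: np.ndarray, species: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Coordinate-wise mean of each species' aligned specimens; species
    order in the output is sorted."""
    aligned = np.asarray(aligned, float)
    uniq = sorted(set(species))
    out = np.array([
        aligned[[i for i, s in enumerate(species) if s == sp]].mean(axis=0)
        for sp in uniq
    ])
    return out, uniq


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1


def shape_pca(shapes: np.ndarray, labels: list[str]) -> PCAResult:
    """Ordinary PCA of the covariance of vectorized aligned coordinates.

    Component signs are fixed by making the largest-magnitude loading
    entry positive; variance fractions sum to 1.
    """
    X = np.asarray(shapes, float).reshape(len(shapes), -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    u, sv, vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.shape[0]
    eig = sv**2 / (n - 1)
    keep = sv > sv[0] * 1e-12 if sv[0] > 0 else slice(0)
    eig = eig[keep]
    loadings = vt[keep].T
    scores = Xc @ loadings
    _fix_signs(loadings, scores)
    frac = eig / eig.sum()
    return PCAResult(mean, eig, loadings, scores, frac, list(labels), "pca")


def phylo_pca(shapes: np.ndarray, labels: list[str], phy: Phylogeny) -> PCAResult:
    """Phylogenetic PCA: eigenvectors of the evolutionary covariance matrix.

    a = (1'C^-1 1)^-1 1'C^-1 X (phylogenetic mean), R = (X - 1a')' C^-1
    (X - 1a') / (n - 1); scores are (X - 1a') V.  Species must match the
    tree tips exactly.
    """
    if sorted(labels) != phy.tip_labels:
        missing = set(phy.tip_labels) ^ set(labels)
        raise ValueError(f"species/tip mismatch: {sorted(missing)}")
    order = np.argsort(np.asarray(labels, dtype=object))
    X = np.asarray(shapes, float).reshape(len(shapes), -1)[order]
    labels_sorted = [labels[i] for i in order]
    C = bm_covariance(phy).matrix
    Cinv = np.linalg.inv(C)
    n = X.shape[0]
    one = np.ones(n)
    a = (one @ Cinv @ X) / (one @ Cinv @ one)
    Xc = X - np.outer(one, a)
    R = Xc.T @ Cinv @ Xc / (n - 1)
    # eigendecomposition through SVD of the symmetrised small-rank matrix
    eigval, eigvec = np.linalg.eigh((R + R.T) / 2.0)
    order_desc = np.argsort(eigval)[::-1]
    eigval = eigval[order_desc]
    eigvec = eigvec[:, order_desc]
    keep = eigval > max(eigval[0], 0) * 1e-12
    eigval = eigval[keep]
    loadings = eigvec[:, keep]
    scores = Xc @ loadings
    _fix_signs(loadings, scores)
    frac = eigval / eigval.sum()
    return PCAResult(a, eigval, loadings, scores, frac, labels_sorted, "ppca")


def shape_at_score(pca: PCAResult, component: int, score: float) -> np.ndarray:
    """Reconstruct the configuration mean + score * loading_k as (p, 3)."""
    v = pca.mean + score * pca.loadings[:, component]
    return v.reshape(-1, 3)


def project_shape(pca: PCAResult, config: np.ndarray) -> np.ndarray:
    """Scores of an arbitrary configuration in an existing PCA basis."""
    x = np.asarray(config, float).ravel() - pca.mean
    return x @ pca.loadings
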