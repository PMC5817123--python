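"""Mean-shape comparison among morph categories.

Pairwise permutation tests of the Procrustes distance between group mean
shapes, and canonical variate analysis (CVA) of Procrustes coordinates in a
PCA subspace (Procrustes coordinate counts typically exceed specimen counts,
so the within-group covariance must be regularized by dimension reduction
before the canonical eigenproblem is solved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .procrustes_core import procrustes_distance

__all__ = ["PermTestResult", "CVAResult", "mean_shape", "procrustes_distance_permutation_test", "cva"]


@dataclass
class PermTestResult:
    group_a: str
    group_b: str
    procrustes_distance: float
    n_permutations: int
    p_value: float


@dataclass
class CVAResult:
    loadings: np.ndarray  # (q, n_axes) canonical axes in the reduced space basis
    scores: np.ndarray  # (n, n_axes) specimen scores
    group_means: np.ndarray  # (g, n_axes)
    eigenvalues: np.ndarray
    groups: list
    pca_basis: np.ndarray  # (2p, q) back-projection of the retained PCA axes


def mean_shape(coords: np.ndarray) -> np.ndarray:
    """Coordinate-wise mean of aligned shapes, re-scaled to unit centroid size."""
    coords = np.asarray(coords, float)
    if coords.ndim != 3 or coords.shape[0] < 1:
        raise ValueError("coords must be a non-empty (n, p, 2) array")
    m = coords.mean(axis=0)
    m = m - m.mean(axis=0)
    return m / np.sqrt((m**2).sum())


def procrustes_distance_permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n: int = 10_000,
    seed=None,
    labels: tuple[str, str] = ("A", "B"),
) -> PermTestResult:
    """Permutation test of the Procrustes distance between two group mean shapes.

    The null distribution shuffles specimens between the groups (preserving
    group sizes) and recomputes the mean-shape distance; p = (b+1)/(n+1).
    """
    if n < 1:
        raise ValueError("need at least one permutation")
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("both groups need at least 2 specimens")
    obs = procrustes_distance(mean_shape(a), mean_shape(b))
    pooled = np.concatenate([a, b], axis=0)
    na = a.shape[0]
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n):
        perm = rng.permutation(pooled.shape[0])
        d = procrustes_distance(
            mean_shape(pooled[perm[:na]]), mean_shape(pooled[perm[na:]])
        )
        if d >= obs:
            exceed += 1
    return PermTestResult(
        group_a=labels[0],
        group_b=labels[1],
        procrustes_distance=obs,
        n_permutations=n,
        p_value=(exceed + 1) / (n + 1),
    )


def cva(flat_coords: np.ndarray, labels, n_pca_retain: int | None = None) -> CVAResult:
    """Canonical variate analysis of (flattened) Procrustes coordinates.

    The data are first reduced to ``n_pca_retain`` principal components
    (default: the axes covering 95% of variance, capped at n - g - 1), then the
    generalized eigenproblem between-group vs. pooled within-group covariance
    is solved.  Scores are whitened so pooled within-group covariance of the
    canonical scores is the identity.  At most g - 1 canonical axes exist.
    """
    x = np.asarray(flat_coords, float)
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    g = len(groups)
    n = x.shape[0]
    if g < 2:
        raise ValueError("CVA needs at least 2 groups")
    for grp in groups:
        if (labels == grp).sum() < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 specimens")

    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    cap = n - g - 1
    if n_pca_retain is None:
        var = s**2
        cum = np.cumsum(var) / var.sum()
        n_pca_retain = int(np.searchsorted(cum, 0.95) + 1)
    n_pca_retain = max(1, min(n_pca_retain, cap, (s > 1e-12 * s[0]).sum()))
    basis = vt[:n_pca_retain].T
    z = xc @ basis

    grand = z.mean(axis=0)
    q = z.shape[1]
    sw = np.zeros((q, q))
    sb = np.zeros((q, q))
    for grp in groups:
        zi = z[labels == grp]
        mi = zi.mean(axis=0)
        sw += (zi - mi).T @ (zi - mi)
        sb += len(zi) * np.outer(mi - grand, mi - grand)
    sw /= n - g
    sb /= g - 1
    try:
        evals, evecs = linalg.eigh(sb, sw)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "singular within-group covariance; retain fewer PCA axes"
        ) from exc
    order = np.argsort(evals)[::-1][: g - 1]
    evals = np.clip(evals[order], 0.0, None)
    axes = evecs[:, order]
    # scipy's eigh(Sb, Sw) normalizes eigenvectors to a' Sw a = 1: whitened
    scores = (z - grand) @ axes
    means = np.stack([scores[labels == grp].mean(axis=0) for grp in groups])
    return CVAResult(
        loadings=axes,
        scores=scores,
        group_means=means,
        eigenvalues=evals,
        groups=groups,
        pca_basis=basis,
    )
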