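"""Morphological integration statistics.

Escoufier's RV coefficient with a within-block permutation test, two-block
partial least squares (PLS) on the between-block covariance matrix, and PCA
score axes used to summarize score planes (the PLS1 shape plane and the
SVL-HeadCS size plane) by their dominant axis.

All block statistics use centred, UNstandardized covariance matrices, the
standard choice for Procrustes coordinate data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RVResult",
    "PLSResult",
    "PCAResult",
    "escoufier_rv",
    "rv_permutation_test",
    "two_block_pls",
    "pca_scores",
]


def _as_block(block) -> np.ndarray:
    x = np.asarray(block, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("block must be 1- or 2-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("block contains non-finite values")
    if x.shape[0] < 3:
        raise ValueError("blocks need at least 3 rows")
    return x


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a, b = _as_block(a), _as_block(b)
    if a.shape[0] != b.shape[0]:
        raise ValueError("blocks must have equal row counts")
    for name, x in (("A", a), ("B", b)):
        if np.allclose(x, x[0]):
            raise ValueError(f"zero-variance block {name}")
    return a - a.mean(axis=0), b - b.mean(axis=0)


@dataclass
class RVResult:
    rv: float
    n_permutations: int = 0
    p_value: float | None = None


@dataclass
class PLSResult:
    singular_values: np.ndarray
    left_loadings: np.ndarray  # columns are axes
    right_loadings: np.ndarray
    scores_left: np.ndarray  # PLS1 scores
    scores_right: np.ndarray
    pct_sq_cov: np.ndarray
    r_pls1: float
    n_permutations: int = 0
    p_value: float | None = None


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    loadings: np.ndarray  # columns are axes
    scores: np.ndarray
    pct_variance: np.ndarray


def _rv_from_centred(ac: np.ndarray, bc: np.ndarray) -> float:
    sab = ac.T @ bc
    saa = ac.T @ ac
    sbb = bc.T @ bc
    return float(np.trace(sab @ sab.T) / np.sqrt(np.trace(saa @ saa) * np.trace(sbb @ sbb)))


def escoufier_rv(block_a, block_b) -> RVResult:
    """Escoufier's RV: trace(S_AB S_BA) / sqrt(trace(S_AA^2) trace(S_BB^2)).

    A multivariate generalization of the squared correlation: for univariate
    blocks RV = r^2.  Invariant to within-block rotation and to global
    rescaling of either block.
    """
    ac, bc = _check_pair(block_a, block_b)
    return RVResult(rv=_rv_from_centred(ac, bc))


def rv_permutation_test(block_a, block_b, n: int = 10_000, seed=None) -> RVResult:
    """Permutation test of RV = 0 by shuffling the row correspondence of block B.

    p = (#{RV_perm >= RV_obs} + 1) / (n + 1), never exactly zero.
    """
    if n < 1:
        raise ValueError("need at least one permutation")
    ac, bc = _check_pair(block_a, block_b)
    obs = _rv_from_centred(ac, bc)
    rng = np.random.default_rng(seed)
    exceed = 0
    m = ac.shape[0]
    for _ in range(n):
        perm = rng.permutation(m)
        if _rv_from_centred(ac, bc[perm]) >= obs:
            exceed += 1
    return RVResult(rv=obs, n_permutations=n, p_value=(exceed + 1) / (n + 1))


def two_block_pls(block_a, block_b, n_perm: int = 0, seed=None) -> PLSResult:
    """Two-block PLS: SVD of the between-block covariance matrix.

    Scores are projections of the centred blocks on the paired singular
    vectors; ``pct_sq_cov[i] = 100 d_i^2 / sum d^2`` is the share of total
    squared covariance on axis *i*; ``r_pls1`` is the Pearson correlation of
    the paired first-axis scores.  When ``n_perm > 0`` a permutation test of
    r_pls1 = 0 (shuffling block B's rows) is run.
    """
    ac, bc = _check_pair(block_a, block_b)
    m = ac.shape[0]

    def _fit(acm, bcm):
        cov = acm.T @ bcm / (m - 1)
        u, d, vt = np.linalg.svd(cov, full_matrices=False)
        sl = acm @ u[:, 0]
        sr = bcm @ vt[0]
        return u, d, vt.T, sl, sr

    u, d, v, sl, sr = _fit(ac, bc)
    with np.errstate(invalid="ignore"):
        r1 = float(np.corrcoef(sl, sr)[0, 1])
    pct = 100.0 * d**2 / (d**2).sum()

    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(m)
            _, _, _, psl, psr = _fit(ac, bc[perm])
            with np.errstate(invalid="ignore"):
                rp = abs(np.corrcoef(psl, psr)[0, 1])
            if rp >= abs(r1):
                exceed += 1
        p_value = (exceed + 1) / (n_perm + 1)

    return PLSResult(
        singular_values=d,
        left_loadings=u,
        right_loadings=v,
        scores_left=sl,
        scores_right=sr,
        pct_sq_cov=pct,
        r_pls1=r1,
        n_permutations=n_perm,
        p_value=p_value,
    )


def pca_scores(matrix, orient_by=None) -> PCAResult:
    """PCA by eigendecomposition of the covariance matrix of centred columns.

    ``orient_by``: optional covariate; each axis is sign-flipped so its scores
    correlate non-negatively with the covariate.  This pins down the sign
    convention for interpreted axes (e.g. larger centroid size scores high on
    the dominant size axis).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("matrix must be (n >= 2, q >= 2)")
    xc = x - x.mean(axis=0)
    if np.allclose(xc, 0):
        raise ValueError("constant matrix has no principal axes")
    cov = xc.T @ xc / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    scores = xc @ evecs
    if orient_by is not None:
        ref = np.asarray(orient_by, dtype=float)
        for j in range(scores.shape[1]):
            c = np.dot(scores[:, j] - scores[:, j].mean(), ref - ref.mean())
            if c < 0:
                evecs[:, j] *= -1
                scores[:, j] *= -1
    total = evals.sum()
    return PCAResult(
        eigenvalues=evals,
        loadings=evecs,
        scores=scores,
        pct_variance=100.0 * evals / total,
    )
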