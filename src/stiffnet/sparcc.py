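"""Compositional correlation estimation via log-ratio variances.

Relative abundances are compositional: naive correlations between
proportions carry spurious negative bias because columns sum to one.
The estimator implemented here infers correlations between the latent
(basis) abundances from the matrix of log-ratio variances

    T_ij = Var[ log(x_i / x_j) ] = w_i^2 + w_j^2 - 2 r_ij w_i w_j,

solving for basis variances ``w_i^2`` under a sparsity assumption
(most pairs uncorrelated) and then iteratively excluding the most
strongly correlated pairs and re-solving, so that a few strong true
correlations do not distort the basis-variance estimates.

This is a single-point estimate computed on pseudocount-adjusted
proportions (no Dirichlet resampling layer); adequate for network
thresholding, where only the sign and rough magnitude matter.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

_EXCLUSION_THRESHOLD = 0.1
_MIN_BASIS_VARIANCE = 1e-12


def _variation_matrix(log_fracs: np.ndarray) -> np.ndarray:
    """T_ij = var over samples of log(x_i) - log(x_j)."""
    n = log_fracs.shape[0]
    T = np.zeros((n, n))
    for i in range(n):
        diff = log_fracs[i] - log_fracs
        T[i] = diff.var(axis=1, ddof=1)
    return (T + T.T) / 2.0


def _solve_basis(T: np.ndarray, M: np.ndarray,
                 excluded: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve for basis variances given current pair exclusions."""
    t = (T * ~excluded).sum(axis=1)
    omega2 = np.linalg.solve(M, t)
    omega2 = np.maximum(omega2, _MIN_BASIS_VARIANCE)
    omega = np.sqrt(omega2)
    denom = 2.0 * np.outer(omega, omega)
    corr = (omega2[:, None] + omega2[None, :] - T) / denom
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return omega2, corr


def sparcc_correlations(fractions: np.ndarray, pseudocount: float = 1e-6,
                        exclusion_iterations: int = 10,
                        exclusion_threshold: float = _EXCLUSION_THRESHOLD
                        ) -> np.ndarray:
    """Basis correlation matrix for a taxa x samples proportion matrix.

    Parameters
    ----------
    fractions : ndarray (n_taxa, n_samples)
        Relative abundances; zeros replaced by ``pseudocount`` and
        columns renormalized before the log transform.
    pseudocount : float
        Replacement for zero proportions.
    exclusion_iterations : int
        Maximum number of strongly-correlated-pair exclusion rounds.
    exclusion_threshold : float
        Pairs with estimated ``|corr|`` above this are candidates for
        exclusion from the basis-variance system.

    Returns
    -------
    ndarray (n_taxa, n_taxa) symmetric, unit diagonal, in [-1, 1].
    """
    fractions = np.asarray(fractions, dtype=float)
    n = fractions.shape[0]
    if n < 4:
        raise ValueError("compositional estimation needs >= 4 taxa")
    filled = np.where(fractions <= 0, pseudocount, fractions)
    filled = filled / filled.sum(axis=0)
    T = _variation_matrix(np.log(filled))

    # linear system for basis variances: t_i ~ (n-2) w_i^2 + sum_k w_k^2
    M = np.full((n, n), 1.0) + np.diag(np.full(n, float(n - 2)))
    excluded = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(excluded, True)

    omega2, corr = _solve_basis(T, M, excluded)
    for _ in range(exclusion_iterations):
        cand = np.abs(corr.copy())
        cand[excluded] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        # drop the strongest pair from both equations and re-solve
        excluded[i, j] = excluded[j, i] = True
        for k in (i, j):
            M[k, k] -= 1.0
        M[i, j] -= 1.0
        M[j, i] -= 1.0
        if min(M[i, i], M[j, j]) < 2:
            logger.warning("exclusion stopped: taxon basis nearly depleted")
            break
        omega2, corr = _solve_basis(T, M, excluded)
    return corr
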