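"""Linear dimensionality-reduction baselines: PCA, PPCA and FA.

These are the reference methods the dropout-aware model is compared
against, and the FA fit doubles as the EM initializer.  PCA is the plain
eigendecomposition; PPCA is the closed-form maximum-likelihood solution
(single shared noise variance); FA has per-gene noise and is fitted with
scikit-learn.

PPCA and FA are generative, so their posterior predictive distribution can
be sampled (:func:`sample_predictive`) — a plain Gaussian law with no
dropout stage, which is exactly the mismatch a zero-inflated model exposes
on sparse data.  PCA has no probabilistic predictive distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA, FactorAnalysis

from .model import _as_values

__all__ = [
    "LinearEmbeddingResult",
    "fit_pca",
    "fit_ppca",
    "fit_fa",
    "sample_predictive",
]


@dataclass
class LinearEmbeddingResult:
    """A fitted linear embedding y ~= loadings @ z + means (+ noise)."""

    method: str  # "pca" | "ppca" | "fa"
    loadings: np.ndarray  # (D, K)
    means: np.ndarray  # (D,)
    noise: np.ndarray | float  # (D,) for FA, scalar for PPCA, 0.0 for PCA
    Z_hat: np.ndarray  # (N, K)
    converged: bool = True

    @property
    def K(self) -> int:
        return self.loadings.shape[1]

    @property
    def generative(self) -> bool:
        """Whether the method defines a probabilistic predictive law."""
        return self.method in ("ppca", "fa")


def fit_pca(y, K: int) -> LinearEmbeddingResult:
    """Top-K principal directions of the column-centered data."""
    Y = _as_values(y)
    N, D = Y.shape
    if not 1 <= K <= min(N - 1, D):
        raise ValueError(f"need 1 <= K <= min(N-1, D) = {min(N - 1, D)}, got {K}")
    pca = PCA(n_components=K, svd_solver="full")
    Z = pca.fit_transform(Y)
    return LinearEmbeddingResult(
        method="pca",
        loadings=pca.components_.T,
        means=pca.mean_,
        noise=0.0,
        Z_hat=Z,
    )


def fit_ppca(y, K: int) -> LinearEmbeddingResult:
    """Closed-form maximum-likelihood probabilistic PCA.

    The ML loadings are ``U_K (L_K - sigma2 I)^(1/2)`` where ``U_K, L_K``
    hold the top-K eigenpairs of the sample covariance and ``sigma2`` is
    the mean of the discarded eigenvalues.  ``Z_hat`` holds the posterior
    means ``M^-1 W^T (y - mu)`` with ``M = W^T W + sigma2 I``.
    """
    Y = _as_values(y)
    N, D = Y.shape
    if not 1 <= K < min(N, D):
        raise ValueError(f"PPCA needs 1 <= K < min(N, D) = {min(N, D)}, got {K}")
    mu = Y.mean(axis=0)
    Yc = Y - mu
    # eigenvalues of the sample covariance Yc^T Yc / N via SVD
    _, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    evals = np.zeros(D)
    evals[: len(s)] = s**2 / N
    sigma2 = float(np.mean(evals[K:]))
    gap = np.maximum(evals[:K] - sigma2, 0.0)
    W = Vt[:K].T * np.sqrt(gap)  # (D, K)
    M = W.T @ W + sigma2 * np.eye(K)
    Z = np.linalg.solve(M, W.T @ Yc.T).T
    return LinearEmbeddingResult(
        method="ppca", loadings=W, means=mu, noise=sigma2, Z_hat=Z
    )


def fit_fa(y, K: int, seed: int | None = 0, max_iter: int = 1000) -> LinearEmbeddingResult:
    """Maximum-likelihood factor analysis with per-gene noise variances."""
    Y = _as_values(y)
    N, D = Y.shape
    if not 1 <= K <= D:
        raise ValueError(f"need 1 <= K <= D, got K={K}, D={D}")
    rs = None if seed is None else int(seed)
    fa = FactorAnalysis(n_components=K, random_state=rs, max_iter=max_iter)
    Z = fa.fit_transform(Y)
    return LinearEmbeddingResult(
        method="fa",
        loadings=fa.components_.T,
        means=fa.mean_,
        noise=np.asarray(fa.noise_variance_),
        Z_hat=Z,
        converged=fa.n_iter_ < max_iter,
    )


def sample_predictive(
    result: LinearEmbeddingResult, n_cells: int, seed: int | None = None
) -> np.ndarray:
    """Draw new cells from a fitted PPCA/FA model's generative law.

    ``z ~ Normal(0, I)``, ``y = loadings z + means + noise`` — no dropout
    stage.  PCA is rejected: it has no probabilistic generative model.
    """
    if not result.generative:
        raise ValueError(
            f"{result.method} has no probabilistic predictive distribution; "
            "use PPCA, FA or the zero-inflated model"
        )
    rng = np.random.default_rng(seed)
    D, K = result.loadings.shape
    Z = rng.standard_normal((n_cells, K))
    noise_sd = np.sqrt(np.broadcast_to(np.asarray(result.noise, dtype=float), (D,)))
    eps = rng.standard_normal((n_cells, D)) * noise_sd
    return Z @ result.loadings.T + result.means + eps
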