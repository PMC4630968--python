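"""EM inference for zero-inflated factor analysis.

The E-step exploits the structure of the posterior: conditionally on the
latent position ``z``, every gene contributes an independent factor — a
Gaussian likelihood at nonzero entries, a squared-exponential-modulated
Gaussian at zero entries.  The modulated factor integrates to a Gaussian
pseudo-observation of 0 with noise variance inflated by ``1/(2*lam)``
(see :func:`zifa.model.zi_gauss_moments`), so the posterior over ``z`` is
Gaussian and computable in O(D K^2) per cell, and the hidden ``x`` values
at zero entries are conditionally independent Gaussians given ``z``.

Two fitting variants are provided:

* :func:`fit_exact` — the E-step conditions on all genes jointly; the
  observed-data log-likelihood is guaranteed non-decreasing.
* :func:`fit_block` — genes are randomly partitioned into blocks and each
  block computes its own posterior from its genes alone; the per-block
  Gaussian posteriors over ``z`` are pooled by precision-weighted
  combination with the prior counted exactly once.  Per-gene moment
  statistics come from the gene's own block, keeping every M-step update a
  consistent conditional-moment system.  Cost is linear in the number of
  genes at fixed block size.

The tied-variance option (one shared noise variance across genes) gives the
zero-inflated analogue of probabilistic PCA (ZI-PPCA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .data_io import ExpressionMatrix
from .model import ModelParams, observed_loglik, _as_values

__all__ = [
    "LatentPosterior",
    "EMState",
    "BlockPartition",
    "e_step_exact",
    "e_step_block",
    "m_step",
    "initialize",
    "make_blocks",
    "fit_exact",
    "fit_block",
]

SIGMA2_FLOOR = 1e-6  # prevents variance collapse on near-constant genes
LAM_BOUNDS = (1e-8, 20.0)  # search interval for the dropout decay
LAM_DEFAULT_INIT = 0.01  # fallback when the data carry no zeros


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class BlockPartition:
    """Disjoint ordered gene-index sets covering all genes."""

    blocks: list[np.ndarray]
    block_size: int

    def __post_init__(self) -> None:
        all_idx = np.concatenate(self.blocks)
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("blocks overlap")


def make_blocks(D: int, block_size: int, seed: int | None = None) -> BlockPartition:
    """Randomly permute genes and chunk into blocks of ``block_size``.

    The last block may be smaller.  Deterministic under ``seed``.
    """
    if not 1 <= block_size <= D:
        raise ValueError(f"need 1 <= block_size <= D, got {block_size} vs D={D}")
    perm = np.random.default_rng(seed).permutation(D)
    blocks = [perm[i : i + block_size] for i in range(0, D, block_size)]
    return BlockPartition(blocks=blocks, block_size=block_size)


@dataclass
class _BlockMoments:
    """Moments of one gene block under that block's own posterior.

    These are the statistics each gene's M-step update is paired with, so
    that every per-gene update is a consistent conditional-moment system.
    """

    idx: np.ndarray  # gene indices of the block
    Ez: np.ndarray  # (N, K) block-posterior means of z
    Ezz: np.ndarray  # (N, K, K)
    Ex: np.ndarray  # (N, B) completed first moments of the block's x
    Ex2: np.ndarray  # (N, B)
    Exz: np.ndarray  # (N, B, K)
    zero: np.ndarray  # (N, B)


@dataclass
class LatentPosterior:
    """Posterior moments of (z, hidden x) given Y and Theta.

    The top-level moments are the algorithm's reported expectations:
    ``Ez``/``Ezz`` from the (pooled) posterior over the latent position,
    and ``Ex``/``Ex2``/``Exz`` *completed* matrices — the observed value
    (y, y^2, y*E[z]) at nonzero entries, the posterior moments of the
    hidden expression at zero entries, imputed under the pooled posterior.

    ``blocks`` additionally records each block's moments under its own
    local posterior; the M-step consumes those, which is where the block
    approximation actually bites.  The exact E-step has a single block
    covering all genes, and the pooled and block-local moments coincide.
    """

    Ez: np.ndarray  # (N, K) pooled posterior means of z
    Ezz: np.ndarray  # (N, K, K) pooled second moments E[z z^T]
    Ex: np.ndarray  # (N, D) completed first moments of x
    Ex2: np.ndarray  # (N, D) completed second moments
    Exz: np.ndarray  # (N, D, K) completed cross-moments E[x z^T]
    zero_mask: np.ndarray  # (N, D) True where y == 0
    blocks: list[_BlockMoments] = field(repr=False)

    @property
    def Ex0(self) -> np.ndarray:
        """Posterior means of x at the zero entries (flat)."""
        return self.Ex[self.zero_mask]

    @property
    def Ex0sq(self) -> np.ndarray:
        """Posterior second moments of x at the zero entries (flat)."""
        return self.Ex2[self.zero_mask]


def _x_moments(A, mu, sig2, lam, Yb, zero, Ez, Ezz):
    """Completed x-moments given z-moments of a Gaussian posterior.

    At zero entries, x | z is Gaussian with mean
    ``(A_j z + mu_j) / (1 + 2 lam sig2_j)`` and variance
    ``sig2_j / (1 + 2 lam sig2_j)``; at nonzero entries x is observed.
    """
    denom = 1.0 + 2.0 * lam * sig2  # (B,)
    proj = Ez @ A.T  # (N, B) = A_j . Ez_i
    q = np.einsum("dk,nkl,dl->nd", A, Ezz, A)  # E[(A_j z)^2]
    mhat = (proj + mu) / denom
    svar = sig2 / denom
    Ex2_zero = svar + (q + 2.0 * mu * proj + mu**2) / denom**2
    Ex = np.where(zero, mhat, Yb)
    Ex2 = np.where(zero, Ex2_zero, Yb**2)
    Exz_zero = (np.einsum("nkl,dl->ndk", Ezz, A) + mu[None, :, None] * Ez[:, None, :]) / denom[
        None, :, None
    ]
    Exz = np.where(zero[..., None], Exz_zero, Yb[..., None] * Ez[:, None, :])
    return Ex, Ex2, Exz


def _block_posterior(params: ModelParams, Y: np.ndarray, idx: np.ndarray):
    """Posterior computations using only the genes in ``idx``.

    Returns the natural parameters (precision, information vector) of the
    z-posterior plus the block's moments under its own posterior.
    """
    A = params.A[idx]  # (B, K)
    mu = params.mu[idx]
    sig2 = params.sigma2[idx]
    lam = params.lam
    Yb = Y[:, idx]  # (N, B)
    zero = Yb == 0.0
    K = params.K

    if lam > 0:
        psi = np.where(zero, sig2 + 0.5 / lam, sig2)
    else:
        psi = np.broadcast_to(sig2, Yb.shape)
    W = 1.0 / psi
    r = Yb - mu  # pseudo-observation 0 at zero entries

    Lam = np.eye(K) + np.einsum("nd,dk,dl->nkl", W, A, A)  # (N, K, K)
    eta = np.einsum("nd,dk->nk", W * r, A)  # (N, K)
    try:
        Cov = np.linalg.inv(Lam)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            "singular posterior precision; consider filtering very sparse genes"
        ) from exc
    Ez = np.einsum("nkl,nl->nk", Cov, eta)
    Ezz = Cov + np.einsum("nk,nl->nkl", Ez, Ez)
    Ex, Ex2, Exz = _x_moments(A, mu, sig2, lam, Yb, zero, Ez, Ezz)
    return Lam, eta, _BlockMoments(idx=idx, Ez=Ez, Ezz=Ezz, Ex=Ex, Ex2=Ex2, Exz=Exz, zero=zero)


def _e_step(params: ModelParams, Y: np.ndarray, partition: list[np.ndarray]) -> LatentPosterior:
    N, D = Y.shape
    K = params.K
    zero_mask = Y == 0.0
    blocks = []
    Lam_pool = np.broadcast_to(np.eye(K), (N, K, K)).copy()
    eta_pool = np.zeros((N, K))
    for idx in partition:
        Lam, eta, bm = _block_posterior(params, Y, idx)
        blocks.append(bm)
        # prior precision I is counted exactly once in the pool
        Lam_pool += Lam - np.eye(K)
        eta_pool += eta
    if len(partition) == 1:
        bm = blocks[0]
        Ez, Ezz = bm.Ez, bm.Ezz
        # scatter the block's (possibly permuted) columns back to gene order
        Ex = np.empty((N, D))
        Ex2 = np.empty((N, D))
        Exz = np.empty((N, D, K))
        Ex[:, bm.idx] = bm.Ex
        Ex2[:, bm.idx] = bm.Ex2
        Exz[:, bm.idx, :] = bm.Exz
    else:
        Cov = np.linalg.inv(Lam_pool)
        Ez = np.einsum("nkl,nl->nk", Cov, eta_pool)
        Ezz = Cov + np.einsum("nk,nl->nkl", Ez, Ez)
        # reported imputations use the pooled posterior, which combines the
        # conditionally independent gene blocks without loss
        Ex, Ex2, Exz = _x_moments(
            params.A, params.mu, params.sigma2, params.lam, Y, zero_mask, Ez, Ezz
        )
    return LatentPosterior(
        Ez=Ez, Ezz=Ezz, Ex=Ex, Ex2=Ex2, Exz=Exz, zero_mask=zero_mask, blocks=blocks
    )


def e_step_exact(params: ModelParams, y) -> LatentPosterior:
    """Exact E-step: one joint posterior per cell conditioning on all genes."""
    Y = _as_values(y)
    if Y.shape[1] != params.D:
        raise ValueError("data/params gene-count mismatch")
    return _e_step(params, Y, [np.arange(params.D)])


def e_step_block(params: ModelParams, y, partition: BlockPartition) -> LatentPosterior:
    """Block-approximate E-step with precision-weighted pooling of z."""
    Y = _as_values(y)
    if Y.shape[1] != params.D:
        raise ValueError("data/params gene-count mismatch")
    return _e_step(params, Y, partition.blocks)


def _lam_objective(lam: float, S_zero: float, ysq_obs: np.ndarray) -> float:
    """Expected complete-log-likelihood terms involving lam (to maximize)."""
    with np.errstate(divide="ignore"):
        obs = np.log1p(-np.exp(-lam * ysq_obs)).sum()
    return -lam * S_zero + obs


def m_step(
    post: LatentPosterior,
    y,
    prev: ModelParams,
    tied_variance: bool = False,
) -> ModelParams:
    """Maximize the expected complete log-likelihood in the posterior moments.

    ``A`` and ``mu`` solve a (K+1)-dimensional linear system per gene;
    ``sigma2`` is the posterior residual second moment (floored at
    ``SIGMA2_FLOOR``); ``lam`` maximizes its expected terms — the dropout
    penalty at imputed zero entries plus ``log(1 - exp(-lam y^2))`` at
    observed entries — by bounded scalar optimization.  With
    ``tied_variance`` the noise variances are pooled into one shared value
    (ZI-PPCA).
    """
    Y = _as_values(y)
    N, D = Y.shape
    K = prev.K
    A_new = np.empty((D, K))
    mu_new = np.empty(D)
    resid = np.empty(D)  # per-gene residual second moments (x N)
    S_zero = 0.0  # sum of E[x^2] over zero entries, block-local moments
    for bm in post.blocks:
        s1 = bm.Ez.sum(axis=0)  # (K,)
        S2 = bm.Ezz.sum(axis=0)  # (K, K)
        G = np.empty((K + 1, K + 1))
        G[:K, :K] = S2
        G[:K, K] = s1
        G[K, :K] = s1
        G[K, K] = N
        tx = bm.Ex.sum(axis=0)  # (B,)
        tx2 = bm.Ex2.sum(axis=0)
        txz = bm.Exz.sum(axis=0)  # (B, K)
        rhs = np.concatenate([txz.T, tx[None, :]], axis=0)  # (K+1, B)
        try:
            beta = np.linalg.solve(G, rhs)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular moment system in the M-step; the latent posterior is "
                "degenerate (try fewer latent dimensions or filter sparse genes)"
            ) from exc
        A_b = beta[:K].T  # (B, K)
        mu_b = beta[K]
        A_new[bm.idx] = A_b
        mu_new[bm.idx] = mu_b
        # At the stationary point the residual second moment simplifies to
        # E[x^2] - A.E[xz] - mu.E[x].
        resid[bm.idx] = tx2 - np.einsum("bk,bk->b", A_b, txz) - mu_b * tx
        S_zero += float(bm.Ex2[bm.zero].sum())

    if tied_variance:
        sigma2_new = np.full(D, max(resid.sum() / (N * D), SIGMA2_FLOOR))
    else:
        sigma2_new = np.maximum(resid / N, SIGMA2_FLOOR)

    # lam update: bounded concave 1-D maximization.
    ysq_obs = np.square(Y[~post.zero_mask])
    res = minimize_scalar(
        lambda lam: -_lam_objective(lam, S_zero, ysq_obs),
        bounds=LAM_BOUNDS,
        method="bounded",
        options={"xatol": 1e-9},
    )
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        raise RuntimeError(
            f"lam optimizer failed on bracket {LAM_BOUNDS}: {res.message}"
        )
    lam_new = float(res.x)
    # guard: never let optimizer tolerance undo an EM ascent step
    if _lam_objective(lam_new, S_zero, ysq_obs) < _lam_objective(prev.lam, S_zero, ysq_obs):
        lam_new = prev.lam
    return ModelParams(A=A_new, mu=mu_new, sigma2=sigma2_new, lam=lam_new)


def expected_complete_loglik(params: ModelParams, post: LatentPosterior, y) -> float:
    """Expected complete-data log-likelihood under the posterior moments.

    Used to verify M-step ascent; entropy terms of the posterior are
    omitted (they do not depend on the parameters).
    """
    Y = _as_values(y)
    N, D = Y.shape
    A, mu, sig2, lam = params.A, params.mu, params.sigma2, params.lam
    # Gaussian term per gene: -N/2 log(2 pi sig2) - resid/(2 sig2)
    total = -0.5 * np.einsum("nkk->", post.Ezz) - 0.5 * N * params.K * np.log(2 * np.pi)
    S_zero = 0.0
    for bm in post.blocks:
        s1 = bm.Ez.sum(axis=0)
        S2 = bm.Ezz.sum(axis=0)
        A_b, mu_b, s2_b = A[bm.idx], mu[bm.idx], sig2[bm.idx]
        tx = bm.Ex.sum(axis=0)
        tx2 = bm.Ex2.sum(axis=0)
        txz = bm.Exz.sum(axis=0)
        quad = (
            tx2
            - 2 * np.einsum("bk,bk->b", A_b, txz)
            - 2 * mu_b * tx
            + np.einsum("bk,kl,bl->b", A_b, S2, A_b)
            + 2 * mu_b * (A_b @ s1)
            + N * mu_b**2
        )
        total += float(np.sum(-0.5 * N * np.log(2 * np.pi * s2_b) - 0.5 * quad / s2_b))
        S_zero += float(bm.Ex2[bm.zero].sum())
    ysq_obs = np.square(Y[~post.zero_mask])
    total += _lam_objective(lam, S_zero, ysq_obs)
    return total


def initialize(y, K: int, seed: int | None = None) -> ModelParams:
    """Data-driven starting point for the EM iterations.

    ``mu`` is the per-gene column mean; ``A`` and ``sigma2`` come from a
    factor-analysis fit that treats zeros as observed values; ``lam`` is a
    least-squares fit of the per-gene zero fraction against
    ``exp(-lam * mbar_j^2)`` where ``mbar_j`` is the gene's mean nonzero
    expression — the empirical dropout-vs-expression relationship.  A
    zero-free matrix carries no dropout signal, so ``lam`` falls back to a
    small default.
    """
    from sklearn.decomposition import FactorAnalysis

    Y = _as_values(y)
    N, D = Y.shape
    if not 1 <= K <= D:
        raise ValueError(f"need 1 <= K <= D, got K={K}, D={D}")
    zero = Y == 0.0
    n_nonzero = (~zero).sum(axis=0)
    if np.any(n_nonzero == 0):
        j = int(np.argmin(n_nonzero))
        raise ValueError(
            f"gene index {j} has no nonzero entries; filter all-zero genes "
            "before fitting (see zifa.data_io.filter_genes)"
        )
    mu0 = Y.mean(axis=0)
    fa = FactorAnalysis(n_components=K, random_state=_to_sklearn_seed(seed))
    fa.fit(Y)
    A0 = fa.components_.T  # (D, K)
    sigma2_0 = np.maximum(fa.noise_variance_, SIGMA2_FLOOR)

    phat = zero.mean(axis=0)
    if np.all(phat == 0):
        lam0 = LAM_DEFAULT_INIT
    else:
        with np.errstate(invalid="ignore"):
            mbar = np.where(n_nonzero > 0, Y.sum(axis=0) / n_nonzero, 0.0)
        msq = mbar**2

        def sse_log(u):
            return float(np.sum((phat - np.exp(-np.exp(u) * msq)) ** 2))

        # search in log(lam): the fit is sharply peaked at small lam and a
        # linear-scale bounded search can overlook it
        res = minimize_scalar(
            sse_log, bounds=tuple(np.log(LAM_BOUNDS)), method="bounded"
        )
        lam0 = float(np.exp(res.x)) if res.success else LAM_DEFAULT_INIT
    return ModelParams(A=A0, mu=mu0, sigma2=sigma2_0, lam=lam0)


def _to_sklearn_seed(seed: int | None) -> int | None:
    if seed is None:
        return None
    return int(np.random.default_rng(seed).integers(0, 2**31 - 1))


@dataclass
class EMState:
    """Result of an EM fit."""

    params: ModelParams
    iteration: int
    loglik_trace: list[float]
    converged: bool
    posterior: LatentPosterior

    @property
    def Z_hat(self) -> np.ndarray:
        """Posterior-mean latent positions of the fitted model."""
        return self.posterior.Ez


def _fit(
    y,
    K: int,
    partition_fn,
    *,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | None = 0,
    tied_variance: bool = False,
    init: ModelParams | None = None,
    verbose: bool = False,
) -> EMState:
    Y = _as_values(y)
    N, D = Y.shape
    params = init if init is not None else initialize(Y, K, seed=seed)
    partition = partition_fn(D)
    trace: list[float] = []
    converged = False
    post = None
    it = 0
    for it in range(1, max_iter + 1):
        post = _e_step(params, Y, partition)
        params = m_step(post, Y, params, tied_variance=tied_variance)
        ll = observed_loglik(params, Y)
        trace.append(ll)
        if verbose:
            print(f"iter {it:4d}  loglik {ll:.6f}")
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) / (N * D) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"EM did not converge within {max_iter} iterations", ConvergenceWarning
        )
    final_post = _e_step(params, Y, partition)
    return EMState(
        params=params,
        iteration=it,
        loglik_trace=trace,
        converged=converged,
        posterior=final_post,
    )


def fit_exact(
    y,
    K: int,
    *,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | None = 0,
    tied_variance: bool = False,
    init: ModelParams | None = None,
    verbose: bool = False,
) -> EMState:
    """Fit by exact EM: joint E-step over all genes every iteration.

    The observed-data log-likelihood trace is non-decreasing (up to solver
    tolerance).  ``tol`` is the convergence threshold on the change in
    per-entry log-likelihood.
    """
    return _fit(
        y,
        K,
        lambda D: [np.arange(D)],
        max_iter=max_iter,
        tol=tol,
        seed=seed,
        tied_variance=tied_variance,
        init=init,
        verbose=verbose,
    )


def fit_block(
    y,
    K: int,
    block_size: int = 50,
    *,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | None = 0,
    tied_variance: bool = False,
    init: ModelParams | None = None,
    verbose: bool = False,
) -> EMState:
    """Fit by block-approximate EM, linear in the gene count.

    Genes are randomly partitioned once (deterministic under ``seed``) and
    the partition is reused every iteration.  ``block_size = D`` degenerates
    to the exact algorithm.
    """

    def partition_fn(D):
        return make_blocks(D, min(block_size, D), seed=seed).blocks

    return _fit(
        y,
        K,
        partition_fn,
        max_iter=max_iter,
        tol=tol,
        seed=seed,
        tied_variance=tied_variance,
        init=init,
        verbose=verbose,
    )
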