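"""The zero-inflated factor analysis generative model.

A cell's expression profile is generated in three stages:

1. latent position  ``z ~ Normal(0, I_K)``;
2. pre-dropout log expression  ``x | z ~ Normal(A z + mu, W)`` with
   ``W = diag(sigma2_1, ..., sigma2_D)``;
3. dropout  ``h_j | x_j ~ Bernoulli(exp(-lam * x_j**2))`` and the observed
   value ``y_j = x_j`` if ``h_j = 0`` else ``0``.

The double-exponential dropout probability ``exp(-lam * x**2)`` captures the
empirical pattern in single-cell RNA-seq that weakly expressed genes drop
out far more often than strongly expressed ones; the decay parameter ``lam``
is shared across genes.

Because the pre-dropout noise is continuous, an exact zero is identified
with a dropout event with probability one (``x = 0`` exactly has measure
zero), so the observed matrix cleanly splits each cell's genes into directly
observed values (``y != 0``) and masked values (``y == 0``).

The central closed-form identity (:func:`zi_gauss_moments`): a Gaussian
density modulated by the squared-exponential dropout weight,

    Normal(x; m, s2) * exp(-lam * x**2),

is an unnormalised Gaussian with

    mass = (1 + 2*lam*s2)**-0.5 * exp(-lam * m**2 / (1 + 2*lam*s2)),
    mean = m / (1 + 2*lam*s2),
    var  = s2 / (1 + 2*lam*s2).

Equivalently ``mass = sqrt(pi/lam) * Normal(0; m, s2 + 1/(2*lam))``: a zero
entry acts as a pseudo-observation of 0 with its noise variance inflated by
``1/(2*lam)``.  Everything downstream (E-step, marginal likelihood) reduces
to ordinary Gaussian linear algebra through this identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import ExpressionMatrix

__all__ = [
    "ModelParams",
    "LatentState",
    "dropout_prob",
    "zi_gauss_moments",
    "sample",
    "observed_loglik",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class ModelParams:
    """Parameter set Theta = (A, mu, sigma2, lam) of the dropout FA model.

    Attributes
    ----------
    A : (D, K) loadings matrix.
    mu : (D,) gene means on the log-count scale.
    sigma2 : (D,) positive per-gene noise variances (diagonal of W).
    lam : positive dropout decay; ``lam = 0`` is accepted in internal math
        as the pure-FA limit but is never a legal fitted value.
    """

    A: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        self.sigma2 = np.asarray(self.sigma2, dtype=float).ravel()
        self.lam = float(self.lam)
        D, K = self.A.shape
        if self.mu.shape != (D,) or self.sigma2.shape != (D,):
            raise ValueError("A, mu, sigma2 dimensions are inconsistent")
        if not (1 <= K <= D):
            raise ValueError(f"need 1 <= K <= D, got K={K}, D={D}")
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 must be positive elementwise")
        if self.lam < 0:
            raise ValueError("lam must be >= 0 (0 only as the pure-FA limit)")

    @property
    def D(self) -> int:
        return self.A.shape[0]

    @property
    def K(self) -> int:
        return self.A.shape[1]

    # -- JSON round-trip (CLI currency) ---------------------------------
    def to_dict(self) -> dict:
        return {
            "A": self.A.tolist(),
            "mu": self.mu.tolist(),
            "sigma2": self.sigma2.tolist(),
            "lam": self.lam,
            "K": self.K,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(np.array(d["A"]), np.array(d["mu"]), np.array(d["sigma2"]), d["lam"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class LatentState:
    """One draw of the full generative state (Z, X, H, Y)."""

    Z: np.ndarray  # (N, K) latent positions
    X: np.ndarray  # (N, D) pre-dropout expression
    H: np.ndarray  # (N, D) binary dropout mask
    Y: np.ndarray  # (N, D) observed matrix

    def __post_init__(self) -> None:
        if not np.array_equal(self.Y[self.H == 0], self.X[self.H == 0]):
            raise ValueError("Y must equal X where H == 0")
        if np.any(self.Y[self.H == 1] != 0.0):
            raise ValueError("Y must be 0 where H == 1")


def dropout_prob(x, lam: float):
    """Dropout probability ``exp(-lam * x**2)`` of a latent expression x.

    Strictly decreasing in ``|x|`` and in ``lam`` for x != 0; equals 1 at
    x = 0.  Vectorised over ``x``.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    return np.exp(-lam * np.square(x))


def zi_gauss_moments(m, s2, lam: float):
    """Mass, mean and variance of ``Normal(x; m, s2) * exp(-lam x^2)``.

    Parameters are broadcast against each other.  ``lam = 0`` is the proper
    Gaussian limit (mass 1).  The returned variance is always below ``s2``
    (the dropout weight sharpens the density) and the mean sits between 0
    and ``m``.
    """
    m = np.asarray(m, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if np.any(s2 <= 0):
        raise ValueError("s2 must be positive")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    denom = 1.0 + 2.0 * lam * s2
    mass = denom**-0.5 * np.exp(-lam * np.square(m) / denom)
    mean = m / denom
    var = s2 / denom
    return mass, mean, var


def sample(params: ModelParams, n_cells: int, seed: int | None = None) -> LatentState:
    """Draw ``n_cells`` independent cells from the generative model."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    N, D, K = n_cells, params.D, params.K
    Z = rng.standard_normal((N, K))
    X = Z @ params.A.T + params.mu + rng.standard_normal((N, D)) * np.sqrt(params.sigma2)
    H = (rng.random((N, D)) < dropout_prob(X, params.lam)).astype(int)
    Y = np.where(H == 1, 0.0, X)
    return LatentState(Z=Z, X=X, H=H, Y=Y)


def _as_values(y) -> np.ndarray:
    return y.values if isinstance(y, ExpressionMatrix) else np.asarray(y, dtype=float)


def observed_loglik(params: ModelParams, y) -> float:
    """Exact observed-data log-likelihood ``log p(Y | Theta)``.

    Integrating out ``(z, x, h)`` per cell gives a closed-form Gaussian
    marginal: each nonzero entry is a direct observation of ``x_j`` carrying
    an extra factor ``1 - exp(-lam y_j^2)`` (the probability it was *not*
    dropped), and each zero entry contributes the modulated-Gaussian mass,
    i.e. a pseudo-observation of 0 with variance ``sigma2_j + 1/(2 lam)``
    and a constant ``sqrt(pi / lam)``.  The D-dimensional Gaussian marginal
    is evaluated with the Woodbury identity, O(D K^2) per cell.

    ``y`` may be an :class:`~zifa.data_io.ExpressionMatrix` or a bare
    (N, D) array.
    """
    Y = _as_values(y)
    if Y.ndim != 2 or Y.shape[1] != params.D:
        raise ValueError(
            f"data has {Y.shape[-1] if Y.ndim == 2 else '?'} genes, model has {params.D}"
        )
    A, mu, sig2, lam = params.A, params.mu, params.sigma2, params.lam
    N, D = Y.shape
    K = params.K
    zero = Y == 0.0

    # Per-entry effective noise variance and residual (pseudo-observation 0
    # at zero entries).
    if lam > 0:
        psi = np.where(zero, sig2 + 0.5 / lam, sig2)  # (N, D)
    else:
        psi = np.broadcast_to(sig2, Y.shape).copy()
    r = Y - mu  # zero entries: 0 - mu, already correct since Y==0 there

    total = 0.0
    # log-normalising constants outside the Gaussian marginal
    nz = ~zero
    with np.errstate(divide="ignore"):
        obs_term = np.log1p(-np.exp(-lam * np.square(Y, where=nz, out=np.ones_like(Y))))
    if lam > 0:
        total += float(np.sum(obs_term[nz]))
        total += 0.5 * np.log(np.pi / lam) * float(zero.sum())
    # lam == 0: dropout never fires; zero entries then are genuine
    # observations of x == 0 and the model is plain FA.

    # Gaussian marginal per cell via Woodbury: Sigma = diag(psi) + A A^T.
    W = 1.0 / psi  # (N, D)
    WA = W[:, :, None] * A[None, :, :]  # (N, D, K)
    M = np.eye(K) + np.einsum("dk,ndl->nkl", A, WA)  # (N, K, K)
    b = np.einsum("nd,dk->nk", r * W, A)  # (N, K) = A^T W r
    sol = np.linalg.solve(M, b[..., None])[..., 0]  # (N, K)
    quad = np.einsum("nd,nd->n", r * W, r) - np.einsum("nk,nk->n", b, sol)
    _, logdetM = np.linalg.slogdet(M)
    logdet = logdetM + np.log(psi).sum(axis=1)
    total += float(np.sum(-0.5 * (D * _LOG2PI + logdet + quad)))
    return total
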