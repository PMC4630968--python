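"""Synthetic data generators for the simulation studies.

Two generators are provided:

* :func:`simulate_factor_data` — draws data from the factor model with one
  of three dropout mechanisms: the double-exponential model
  ``exp(-lam x^2)`` (the one the zero-inflated model assumes), a linear
  decay ``1 - lam x`` (clipped to [0, 1]), and a per-gene uniform
  missing-at-random mechanism.  The latter two deliberately misspecify the
  dropout model to probe robustness.
* :func:`simulate_cluster_scaffold` — plants well-defined cell clusters in
  the latent space before projection, giving labelled data for the cell
  type separability study.

Defaults are the standard study conditions: loadings ``U(-0.5, 0.5)``,
noise variances ``U(0.9, 1.1) * sigma2``, gene means ``U(2.7, 3.3)``, and
the base setting N=150, K=10, D=50, sigma2=0.3, lam=0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .model import LatentState, ModelParams, dropout_prob

__all__ = [
    "SimConfig",
    "SimOutput",
    "BASE_SETTING",
    "simulate_factor_data",
    "simulate_cluster_scaffold",
]

Mechanism = Literal["double_exponential", "linear", "uniform"]


@dataclass
class SimConfig:
    """Generative settings for a simulation run.

    ``lam`` parameterises the chosen dropout mechanism (decay of the
    double-exponential or linear mechanism).  For the uniform
    (missing-at-random) mechanism, ``uniform_rates`` gives each gene's
    dropout probability directly; left unset, rates are drawn from
    ``U(0.1, 0.5)`` — a realistic spread of per-gene missingness.

    ``n_clusters``/``cluster_separation``/``cluster_spread`` only apply in
    scaffold mode.
    """

    N: int = 150
    D: int = 50
    K: int = 10
    sigma2: float = 0.3
    lam: float = 0.1
    dropout_mechanism: Mechanism = "double_exponential"
    uniform_rates: np.ndarray | None = None
    n_clusters: int | None = None
    cluster_separation: float | None = None
    cluster_spread: float = 1.0
    clip_linear: bool = True
    seed: int | None = 0

    def __post_init__(self) -> None:
        if min(self.N, self.D, self.K) < 1 or self.K > self.D:
            raise ValueError("need N, D >= 1 and 1 <= K <= D")
        if self.sigma2 <= 0 or self.lam < 0:
            raise ValueError("sigma2 must be positive and lam non-negative")
        if self.uniform_rates is not None:
            r = np.asarray(self.uniform_rates, dtype=float)
            if r.shape != (self.D,) or np.any((r < 0) | (r > 1)):
                raise ValueError("uniform_rates must be a D-vector in [0, 1]")
            self.uniform_rates = r


@dataclass
class SimOutput:
    """A generated data set with its ground truth."""

    truth: LatentState
    config: SimConfig
    true_params: ModelParams
    cluster_labels: np.ndarray | None = None

    @property
    def Y(self) -> np.ndarray:
        return self.truth.Y

    @property
    def dropout_rate(self) -> float:
        """Overall fraction of masked entries."""
        return float(self.truth.H.mean())


BASE_SETTING = SimConfig()  # N=150, K=10, D=50, sigma2=0.3, lam=0.1


def _draw_params(cfg: SimConfig, rng: np.random.Generator) -> ModelParams:
    A = rng.uniform(-0.5, 0.5, size=(cfg.D, cfg.K))
    sigma2 = rng.uniform(0.9, 1.1, size=cfg.D) * cfg.sigma2
    mu = rng.uniform(2.7, 3.3, size=cfg.D)
    # true_params.lam records the decay used by the mechanism; for the
    # uniform mechanism it is not a model parameter of the data.
    return ModelParams(A=A, mu=mu, sigma2=sigma2, lam=max(cfg.lam, 1e-12))


def _dropout_probs(cfg: SimConfig, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if cfg.dropout_mechanism == "double_exponential":
        return dropout_prob(X, cfg.lam)
    if cfg.dropout_mechanism == "linear":
        p = 1.0 - cfg.lam * X
        out = (p < 0) | (p > 1)
        if out.any():
            if not cfg.clip_linear:
                raise ValueError(
                    "linear dropout probability 1 - lam*x falls outside [0, 1]; "
                    "set clip_linear=True to clip"
                )
            p = np.clip(p, 0.0, 1.0)
        return p
    if cfg.dropout_mechanism == "uniform":
        rates = cfg.uniform_rates
        if rates is None:
            rates = rng.uniform(0.1, 0.5, size=cfg.D)
        return np.broadcast_to(rates, X.shape)
    raise ValueError(f"unknown dropout mechanism {cfg.dropout_mechanism!r}")


def _apply_dropout(
    cfg: SimConfig, Z: np.ndarray, params: ModelParams, rng: np.random.Generator
) -> LatentState:
    X = Z @ params.A.T + params.mu + rng.standard_normal(
        (Z.shape[0], cfg.D)
    ) * np.sqrt(params.sigma2)
    p0 = _dropout_probs(cfg, X, rng)
    H = (rng.random(X.shape) < p0).astype(int)
    Y = np.where(H == 1, 0.0, X)
    return LatentState(Z=Z, X=X, H=H, Y=Y)


def simulate_factor_data(cfg: SimConfig | None = None, **overrides) -> SimOutput:
    """Generate factor-model data under the configured dropout mechanism.

    Nonzero observed entries equal the pre-dropout values exactly: dropout
    masks, it never perturbs.  Reproducible under ``cfg.seed``.
    """
    cfg = replace(cfg if cfg is not None else BASE_SETTING, **overrides)
    rng = np.random.default_rng(cfg.seed)
    params = _draw_params(cfg, rng)
    Z = rng.standard_normal((cfg.N, cfg.K))
    truth = _apply_dropout(cfg, Z, params, rng)
    return SimOutput(truth=truth, config=cfg, true_params=params)


def simulate_cluster_scaffold(cfg: SimConfig | None = None, **overrides) -> SimOutput:
    """Generate labelled clustered data for the separability study.

    Cluster centers are drawn as ``cluster_separation * Normal(0, I_K)``;
    cells are assigned to clusters uniformly at random and scattered around
    their center with standard deviation ``cluster_spread``.  Projection,
    noise and dropout then proceed exactly as in
    :func:`simulate_factor_data`.
    """
    cfg = replace(cfg if cfg is not None else BASE_SETTING, **overrides)
    if cfg.n_clusters is None or cfg.n_clusters < 2:
        raise ValueError("scaffold mode requires n_clusters >= 2")
    if cfg.cluster_separation is None or cfg.cluster_separation <= 0:
        raise ValueError("scaffold mode requires cluster_separation > 0")
    rng = np.random.default_rng(cfg.seed)
    params = _draw_params(cfg, rng)
    centers = cfg.cluster_separation * rng.standard_normal((cfg.n_clusters, cfg.K))
    labels = rng.integers(0, cfg.n_clusters, size=cfg.N)
    Z = centers[labels] + cfg.cluster_spread * rng.standard_normal((cfg.N, cfg.K))
    truth = _apply_dropout(cfg, Z, params, rng)
    return SimOutput(truth=truth, config=cfg, true_params=params, cluster_labels=labels)
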