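"""Evaluation procedures for latent-space and predictive quality.

Three families of checks:

* **Latent-distance recovery** — dimensionality reduction is only defined
  up to rotation/reflection of the latent space, so embeddings are scored
  by how well they preserve the matrix of pairwise cell-cell distances:
  the Spearman correlation between the true and estimated distance
  matrices, computed on upper-triangle entries.
* **Posterior predictive histogram divergence** — a fitted generative
  model is asked to predict the per-gene distribution of values; observed
  and predicted samples are binned into 30 equal-width intervals over
  their pooled range and compared by the L1 distance between normalized
  histograms (bounded by 2).
* **Consistency and separability studies** — stability of cell-cell
  distances across random gene subsets, and LDA/QDA misclassification of
  known cell types after reduction to a low-dimensional embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)

from . import baselines, em
from .model import _as_values, sample as model_sample
from .simulation import SimOutput

__all__ = [
    "DistanceScore",
    "PredictiveCheck",
    "SeparabilityReport",
    "distance_recovery_score",
    "histogram_divergence",
    "predictive_fit_study",
    "consistency_study",
    "separability_study",
]


# ---------------------------------------------------------------------------
# latent-distance recovery
# ---------------------------------------------------------------------------

@dataclass
class DistanceScore:
    F_true: np.ndarray  # (N, N) true pairwise distances
    F_hat: np.ndarray  # (N, N) estimated pairwise distances
    spearman: float  # rank correlation on strictly-upper-triangle entries
    sse: float  # sum of squared differences (scale-sensitive variant)


def distance_recovery_score(Z_true: np.ndarray, Z_hat: np.ndarray) -> DistanceScore:
    """Score an embedding by rank agreement of pairwise distances.

    Both embeddings may live in spaces of different dimension; only the
    N x N Euclidean distance matrices are compared.  The Spearman score is
    invariant to rotation, reflection, translation and positive scaling of
    either embedding.
    """
    Z_true = np.atleast_2d(np.asarray(Z_true, dtype=float))
    Z_hat = np.atleast_2d(np.asarray(Z_hat, dtype=float))
    if Z_true.shape[0] != Z_hat.shape[0]:
        raise ValueError("embeddings must have the same number of cells")
    if Z_true.shape[0] < 3:
        raise ValueError("need at least 3 cells to correlate pairwise distances")
    d_true = pdist(Z_true)  # condensed = strictly-upper-triangle entries
    d_hat = pdist(Z_hat)
    rho = float(spearmanr(d_true, d_hat).statistic)
    return DistanceScore(
        F_true=squareform(d_true),
        F_hat=squareform(d_hat),
        spearman=rho,
        sse=float(np.sum((d_true - d_hat) ** 2)),
    )


# ---------------------------------------------------------------------------
# posterior predictive histogram divergence
# ---------------------------------------------------------------------------

def histogram_divergence(observed, predicted, n_bins: int = 30) -> float:
    """L1 distance between normalized equal-width histograms, in [0, 2].

    Bins span the pooled min/max of both samples.  If both samples are
    identically constant the divergence is 0 by convention.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.size == 0 or pred.size == 0:
        raise ValueError("both samples must be nonempty")
    lo = min(obs.min(), pred.min())
    hi = max(obs.max(), pred.max())
    if lo == hi:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    h = np.histogram(obs, bins=edges)[0] / obs.size
    h_hat = np.histogram(pred, bins=edges)[0] / pred.size
    return float(np.abs(h - h_hat).sum())


@dataclass
class PredictiveCheck:
    """Per-gene predictive divergences for a set of fitted methods."""

    divergences: dict[str, np.ndarray]  # method -> (D,) Delta_j
    win_fraction: dict[str, float]  # "zifa_vs_<m>" -> share of genes zifa wins
    n_bins: int = 30
    train_fraction: float = 0.70


def _fit_and_predict(method: str, Y_train, n_pred: int, K: int, seed, zifa_kwargs):
    """Fit one method on the training cells and draw predictive cells."""
    if method == "zifa":
        state = em.fit_exact(Y_train, K, seed=seed, **zifa_kwargs)
        return model_sample(state.params, n_pred, seed=seed).Y
    if method == "zifa_block":
        state = em.fit_block(Y_train, K, seed=seed, **zifa_kwargs)
        return model_sample(state.params, n_pred, seed=seed).Y
    if method in ("fa", "ppca"):
        fit = baselines.fit_fa(Y_train, K, seed=seed) if method == "fa" else baselines.fit_ppca(Y_train, K)
        return baselines.sample_predictive(fit, n_pred, seed=seed)
    raise ValueError(
        f"method {method!r} has no posterior predictive distribution; "
        "supported: zifa, zifa_block, fa, ppca"
    )


def predictive_fit_study(
    y,
    K: int = 5,
    methods: tuple[str, ...] = ("zifa", "fa", "ppca"),
    seed: int | None = 0,
    *,
    n_bins: int = 30,
    train_fraction: float = 0.70,
    pred_factor: int = 10,
    **zifa_kwargs,
) -> PredictiveCheck:
    """Held-out posterior predictive check of distributional fit.

    Cells are split 70/30 into train/test; each method is fitted on the
    training cells and asked to generate ``pred_factor`` times the test-set
    size of new cells; per gene, the 30-bin histogram divergence between
    test values and predicted values is recorded.  The zero-inflated model
    predicts through its full law including the dropout stage; FA and PPCA
    predict from their Gaussian law (they have no dropout stage).
    """
    Y = _as_values(y)
    N = Y.shape[0]
    if N < 10:
        raise ValueError("need at least 10 cells for a train/test split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(N)
    n_train = int(round(train_fraction * N))
    train, test = perm[:n_train], perm[n_train:]
    n_pred = pred_factor * len(test)

    divergences: dict[str, np.ndarray] = {}
    for method in methods:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        Y_pred = _fit_and_predict(method, Y[train], n_pred, K, sub_seed, zifa_kwargs)
        divergences[method] = np.array(
            [
                histogram_divergence(Y[test][:, j], Y_pred[:, j], n_bins=n_bins)
                for j in range(Y.shape[1])
            ]
        )

    win_fraction = {}
    if "zifa" in divergences:
        for m, dj in divergences.items():
            if m != "zifa":
                win_fraction[f"zifa_vs_{m}"] = float(
                    np.mean(divergences["zifa"] < dj)
                )
    return PredictiveCheck(
        divergences=divergences,
        win_fraction=win_fraction,
        n_bins=n_bins,
        train_fraction=train_fraction,
    )


# ---------------------------------------------------------------------------
# consistency of cell-cell distances across gene subsets
# ---------------------------------------------------------------------------

def _embed(method: str, Y, K: int, seed, zifa_kwargs) -> np.ndarray:
    if method == "zifa":
        return em.fit_exact(Y, K, seed=seed, **zifa_kwargs).Z_hat
    if method == "zifa_block":
        return em.fit_block(Y, K, seed=seed, **zifa_kwargs).Z_hat
    if method == "ppca":
        return baselines.fit_ppca(Y, K).Z_hat
    if method == "fa":
        return baselines.fit_fa(Y, K, seed=seed).Z_hat
    if method == "pca":
        return baselines.fit_pca(Y, K).Z_hat
    raise ValueError(f"unknown method {method!r}")


@dataclass
class ConsistencyResult:
    """Pairwise distance-matrix correlations across random gene subsets."""

    correlations: dict[str, np.ndarray]  # method -> (n_pairs,) Spearman rhos
    n_repeats: int
    n_failures: dict[str, int] = field(default_factory=dict)


def consistency_study(
    y,
    n_repeats: int = 100,
    subset_size: int = 100,
    methods: tuple[str, ...] = ("zifa", "ppca"),
    seed: int | None = 0,
    K: int = 5,
    **zifa_kwargs,
) -> ConsistencyResult:
    """Stability of embeddings under random gene subsetting.

    For each repeat, ``subset_size`` genes are drawn at random, each method
    is fitted, and the N x N cell distance matrix is recorded.  Every pair
    of repeats is then compared by Spearman correlation —
    ``n_repeats * (n_repeats - 1) / 2`` correlations per method.  A fit
    failure skips that repeat for that method and is counted.
    """
    Y = _as_values(y)
    D = Y.shape[1]
    if D < subset_size:
        raise ValueError(f"need D >= subset_size, got D={D} < {subset_size}")
    rng = np.random.default_rng(seed)
    dist_vecs: dict[str, list[np.ndarray]] = {m: [] for m in methods}
    n_failures = {m: 0 for m in methods}
    for _ in range(n_repeats):
        genes = rng.choice(D, size=subset_size, replace=False)
        Ysub = Y[:, genes]
        # drop genes with no nonzero entries in this subset
        Ysub = Ysub[:, (Ysub != 0).any(axis=0)]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        for m in methods:
            try:
                Z = _embed(m, Ysub, K, sub_seed, zifa_kwargs if m.startswith("zifa") else {})
                dist_vecs[m].append(pdist(Z))
            except Exception:
                n_failures[m] += 1
    correlations = {}
    for m, vecs in dist_vecs.items():
        rhos = [
            float(spearmanr(vecs[a], vecs[b]).statistic)
            for a in range(len(vecs))
            for b in range(a + 1, len(vecs))
        ]
        correlations[m] = np.array(rhos)
    return ConsistencyResult(
        correlations=correlations, n_repeats=n_repeats, n_failures=n_failures
    )


# ---------------------------------------------------------------------------
# cell type separability
# ---------------------------------------------------------------------------

@dataclass
class SeparabilityReport:
    """Training misclassification rates of discriminant classifiers on
    low-dimensional embeddings, per random gene subset.

    ``errors[(method, classifier)]`` is an ``(n_subsets,)`` array; NaN marks
    a subset where the classifier failed (e.g. singular class covariance
    under QDA).  ``baseline_errors`` holds the dropout-free exact-PCA
    reference when requested.
    """

    errors: dict[tuple[str, str], np.ndarray]
    dropout_rates: np.ndarray  # per-subset fraction of zeros in the input
    baseline_errors: np.ndarray | None = None
    classifiers: tuple[str, ...] = ("lda", "qda")


def _train_error(classifier: str, Z: np.ndarray, labels: np.ndarray) -> float:
    if classifier == "lda":
        clf = LinearDiscriminantAnalysis()
    elif classifier == "qda":
        clf = QuadraticDiscriminantAnalysis()
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    clf.fit(Z, labels)
    return float(1.0 - clf.score(Z, labels))


def separability_study(
    sim: SimOutput,
    K_out: int = 10,
    subset_size: int = 500,
    n_subsets: int = 30,
    classifiers: tuple[str, ...] = ("lda", "qda"),
    seed: int | None = 0,
    methods: tuple[str, ...] = ("pca", "zifa_block"),
    include_exact_baseline: bool = True,
    baseline_classifier: str = "qda",
    **zifa_kwargs,
) -> SeparabilityReport:
    """Cell type separability after dimensionality reduction.

    For each of ``n_subsets`` random gene subsets of size ``subset_size``,
    the observed (zero-inflated) data are reduced to ``K_out`` dimensions
    by each method, discriminant classifiers are trained on the embedding
    against the true cluster labels, and the *training* misclassification
    rate is recorded as the separability measure.  The optional baseline
    applies plain PCA to the dropout-free latent expression ``X`` on the
    same genes — the ground-truth reference unaffected by dropout.
    """
    if sim.cluster_labels is None:
        raise ValueError("separability_study requires a simulation with cluster labels")
    Y, X, labels = sim.truth.Y, sim.truth.X, sim.cluster_labels
    D = Y.shape[1]
    if D < subset_size:
        raise ValueError(f"need D >= subset_size, got D={D} < {subset_size}")
    rng = np.random.default_rng(seed)
    errors = {(m, c): np.full(n_subsets, np.nan) for m in methods for c in classifiers}
    baseline = np.full(n_subsets, np.nan) if include_exact_baseline else None
    dropout_rates = np.empty(n_subsets)
    for s in range(n_subsets):
        genes = rng.choice(D, size=subset_size, replace=False)
        keep = (Y[:, genes] != 0).any(axis=0)
        genes = genes[keep]
        Ysub = Y[:, genes]
        dropout_rates[s] = float((Ysub == 0).mean())
        sub_seed = int(rng.integers(0, 2**31 - 1))
        for m in methods:
            try:
                Z = _embed(m, Ysub, K_out, sub_seed, zifa_kwargs if m.startswith("zifa") else {})
            except Exception:
                continue  # NaN already marks the failure
            for c in classifiers:
                try:
                    errors[(m, c)][s] = _train_error(c, Z, labels)
                except Exception:
                    pass
        if baseline is not None:
            Zb = baselines.fit_pca(X[:, genes], K_out).Z_hat
            baseline[s] = _train_error(baseline_classifier, Zb, labels)
    return SeparabilityReport(
        errors=errors,
        dropout_rates=dropout_rates,
        baseline_errors=baseline,
        classifiers=tuple(classifiers),
    )
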