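# Methods

## Model

Each cell's observed log-expression profile `y` arises from a latent
position `z ~ N(0, I_K)` projected into gene space, `x | z ~ N(Az + mu, W)`
with diagonal `W`, after which every entry is independently masked to zero
with probability `exp(-lam * x^2)`. The decay `lam` is shared across genes:
dropout is treated as a technology-level property, with its gene-to-gene
variation carried by the gene means (lowly expressed genes sit closer to
zero and drop out more). Working assumptions:

* Values are log read counts, non-negative, already transformed. The
  package never chooses a log base or pseudocount for the user; an
  explicit `log1p` flag is the only transform offered.
* An exact zero is identified with a dropout event with probability one:
  under the continuous noise model, `x = 0` exactly has measure zero, so
  the observed matrix splits cleanly into directly observed entries
  (`y != 0`, where `x = y`) and masked entries (`y == 0`, `x` hidden).
* `lam = 0` (pure FA) is accepted in internal computations as a limit but
  is not a legal fitted value; the fitted `lam` is confined to
  `[1e-8, 20]`. At the upper end dropout is already negligible for any
  realistic expression level (`exp(-20 * 9) ~ 1e-79`), so the bound is not
  a practical restriction; it exists because zero-free data push the
  maximum-likelihood `lam` to infinity.

## The modulated-Gaussian identity

All inference rests on one identity: for the density proportional to
`N(x; m, s2) * exp(-lam x^2)`,

```
mass = (1 + 2 lam s2)^(-1/2) exp(-lam m^2 / (1 + 2 lam s2))
mean = m / (1 + 2 lam s2)
var  = s2 / (1 + 2 lam s2)
```

and equivalently `mass = sqrt(pi/lam) * N(0; m, s2 + 1/(2 lam))`. A zero
entry therefore behaves as a Gaussian pseudo-observation of 0 with noise
variance inflated by `1/(2 lam)`. The identity is verified against
adaptive quadrature to better than 1e-8 over a wide parameter grid (see
the acceptance tests).

## E-step

Conditioned on `z`, the genes are independent; each nonzero entry
contributes `N(y_j; A_j z + mu_j, sigma_j^2)` and each zero entry — after
integrating out the hidden `x` — `sqrt(pi/lam) * N(0; A_j z + mu_j,
sigma_j^2 + 1/(2 lam))`. The posterior over `z` is therefore Gaussian,
with precision `I + A^T Psi^{-1} A` where `Psi` holds the per-entry
effective variances, computed per cell in O(D K^2). Given `z`, the hidden
`x` at a zero entry is Gaussian with mean `(A_j z + mu_j)/(1 + 2 lam
sigma_j^2)` and variance `sigma_j^2/(1 + 2 lam sigma_j^2)`; the posterior
moments `E[x]`, `E[x^2]`, `E[x z]` follow from the z-moments. No sampling
and no factorisation across genes is involved: the E-step is exact, and it
is validated against a brute-force importance-sampling oracle on small
instances.

The observed-data log-likelihood has the same structure: a D-dimensional
Gaussian marginal per cell (evaluated with the Woodbury identity) times
the per-entry normalisers — `1 - exp(-lam y^2)` for each nonzero entry,
`sqrt(pi/lam)` per zero entry.

## M-step

Maximising the expected complete log-likelihood gives, per gene, a
(K+1)-dimensional linear system in the sufficient statistics for
`(A_j, mu_j)`, and the posterior residual second moment for `sigma_j^2`
(floored at 1e-6 to prevent collapse on near-constant genes; the tied
variant pools the residuals into one shared variance, giving ZI-PPCA).
The `lam`-terms —

```
sum over zero entries of -lam E[x^2]  +  sum over nonzero entries of log(1 - exp(-lam y^2))
```

— are concave in `lam` and maximised by bounded Brent search on
`[1e-8, 20]`. The `log(1 - exp(-lam y^2))` terms for *observed* entries
are retained both here and in the likelihood; dropping them would bias
`lam` upward, because observing a value at all is evidence against
dropout. A guard keeps the previous `lam` if the scalar optimiser's
tolerance would ever produce a lower objective value, preserving the EM
ascent property to numerical precision.

## Exact vs block EM

The exact fit conditions on all genes jointly in every E-step. The block
variant partitions genes into random disjoint blocks (fixed once per fit,
deterministic under the seed) and computes each block's posterior from its
own genes alone; per-gene M-step statistics come from the gene's own
block, so each update remains a consistent conditional-moment system and
the cost is linear in the gene count at fixed block size. The per-block
Gaussian z-posteriors are then pooled by precision-weighted combination
with the prior counted exactly once. Because genes are conditionally
independent given `z`, this pooling loses nothing for the latent position,
and the *reported* expectations (the embedding `Z_hat` and the imputed
`x`-moments) are computed under the pooled posterior. The approximation
therefore lives in the parameter updates, not in the reported moments;
with block size equal to the gene count the two algorithms coincide. On
500 genes × 200 cells with block size 50 the two variants' reported
expectations correlate above 0.98 despite genuinely different iteration
paths.

Monotonicity of the observed-data log-likelihood is guaranteed (and
asserted in tests, slack 1e-8) for the exact variant only; the block
variant's trace is empirically well-behaved but carries no guarantee.

## Initialization and convergence

* `mu`: column means of the observed matrix (zeros included).
* `A`, `sigma2`: a factor-analysis fit treating zeros as observed values.
* `lam`: least squares of the per-gene zero fraction against
  `exp(-lam * mbar_j^2)`, `mbar_j` the gene's mean nonzero expression.
  The search runs on `log(lam)` — the objective is sharply dipped at
  small `lam` and a linear-scale bounded search can skip the dip
  entirely. A zero-free matrix carries no dropout signal and falls back
  to `lam = 0.01`. Note the estimator is biased low (the mean *nonzero*
  expression is upward-selected), typically within a factor of two at
  realistic noise — adequate for a starting point; EM refines it to a few
  percent.
* Convergence: the fit stops when the change in *per-entry* observed
  log-likelihood falls below 1e-6 (configurable), or after 200 iterations
  with a warning and `converged=False`.
* Genes with no nonzero entries are rejected before fitting; the gene
  filter removes genes that are zero in more than 95 % of cells by
  default (an 80 % threshold is the fallback for data sets where very
  sparse genes destabilise the fit).

## Identifiability

Factor models are defined only up to rotation of the latent space, and no
rotation constraint is imposed on `A`. Every evaluation is correspondingly
rotation-invariant: embeddings are compared through pairwise cell–cell
distance matrices (Spearman correlation of upper-triangle entries, average
ranks on ties), and loadings through principal subspace angles.

## Synthetic data

`simulate_factor_data` draws loadings from `U(-0.5, 0.5)`, noise variances
from `U(0.9, 1.1) * sigma2`, and gene means from `U(2.7, 3.3)`; the
default configuration is N=150 cells, D=50 genes, K=10, `sigma2=0.3`,
`lam=0.1` (about 43 % dropout). Three dropout mechanisms are provided:
the double-exponential law the model assumes; a linear decay `1 - lam x`,
clipped to [0, 1] since it is not otherwise a probability; and a
missing-at-random mechanism with constant per-gene dropout probabilities
(drawn from `U(0.1, 0.5)` when unspecified — a realistic spread of
per-gene missingness). The last two deliberately misspecify the model to
probe robustness. `simulate_cluster_scaffold` plants cluster centers at
`separation * N(0, I_K)` in latent space, assigns cells uniformly, and
scatters them with unit spread before projection and dropout, yielding
labelled data for the separability study.

What the generator does *not* emulate: count-level noise (everything is
Gaussian on the log scale), library-size variation and normalisation
artefacts, UMI-specific zero profiles, near-zero-but-nonzero measurements,
batch effects, or non-linear latent structure. Passing tests demonstrate
correct inference under the model's own assumptions and graceful
degradation under misspecified dropout — not performance on any particular
real data set.

## Evaluation choices

* Histogram divergence: 30 equal-width bins spanning the pooled min/max
  of the observed and predicted samples; the divergence is the L1
  distance between the two normalised histograms, bounded by 2; an
  identically constant pair scores 0 by convention.
* Posterior predictive draws: each fitted generative model (ZIFA with its
  dropout stage, FA/PPCA without one) generates 10× the test-set size per
  gene, keeping the Monte-Carlo error of the divergence small relative to
  bin mass. PCA is rejected: it has no predictive distribution.
* The predictive check splits cells 70/30 into train/test.
* Separability is the *training* misclassification rate of LDA/QDA on the
  embedding — a direct measure of class overlap in the reduced space.
* Study sizes used by the acceptance script and tests: distance-recovery
  and predictive studies at the default simulation setting; block-vs-exact
  on 500 genes × 200 cells; separability on 200-cell, 600-gene scaffolds
  with four clusters at separation 1.0 (a weakly separated regime),
  aggregated over several scaffold draws because individual draws vary in
  how separable the planted clusters come out; consistency at 10 repeats
  (45 distance-matrix pairs per method).

## Known limitations

* Only exact zeros are modelled; near-zero measurements are ordinary
  Gaussian observations.
* One shared `lam`; per-gene dropout rates appear only in the
  missing-at-random simulator, not in the fitted model.
* No parallel or stochastic/mini-batch EM; the implementation is serial
  NumPy.
* The blockwise fit depends (weakly) on the random gene partition; two
  block fits with different seeds can differ beyond solver tolerance.
* QDA-based separability requires enough cells per class relative to the
  embedding dimension; singular class covariances are reported as failed
  subsets rather than repaired.
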