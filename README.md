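# zifa — zero-inflated factor analysis for single-cell expression data

Single-cell RNA-seq expression matrices are riddled with exact zeros:
*dropout events* caused by technical sampling of scarce transcripts or
bursty transcription. Standard linear dimensionality reduction — PCA,
probabilistic PCA (PPCA), factor analysis (FA) — treats those zeros as
ordinary measurements and distorts the latent structure of the data.
This package implements **zero-inflated factor analysis (ZIFA)**: a factor
model with an explicit dropout stage, fitted by an EM algorithm, together
with the simulation and evaluation machinery to quantify when dropout-aware
reduction matters.

It is aimed at computational biologists analysing log-transformed
single-cell expression matrices, and at methodologists who need a
well-tested reference implementation of the model.

## The model

For cells *i* = 1…N and genes *j* = 1…D, with K latent dimensions:

```
z_i  ~ Normal(0, I_K)                      latent position
x_i | z_i ~ Normal(A z_i + mu, W)          pre-dropout log expression
h_ij | x_ij ~ Bernoulli(exp(-lam x_ij^2))  dropout indicator
y_ij = x_ij if h_ij = 0, else 0            observed value
```

`A` (D×K) are factor loadings, `mu` gene means, `W = diag(sigma_j^2)`
per-gene noise variances, and `lam > 0` a decay parameter shared across
genes. The double-exponential dropout law `p0 = exp(-lam x^2)` captures
the empirical pattern that weakly expressed genes drop out far more often.
Tying the noise variances (`sigma_j^2 = sigma^2`) gives the zero-inflated
analogue of PPCA (ZI-PPCA).

Everything stays analytically tractable because a Gaussian density
modulated by the dropout weight is again an (unnormalised) Gaussian: a
zero entry acts as a pseudo-observation of 0 with its variance inflated by
`1/(2 lam)`. The E-step, the observed-data likelihood, and the fast
block-approximate variant (cost linear in the number of genes) all reduce
to ordinary Gaussian linear algebra. See `docs/methods.md` for the
derivations and numerical choices.

## Worked example

```python
import zifa

# standard simulation setting: N=150 cells, D=50 genes, K=10,
# sigma2=0.3, lam=0.1 -- about 43% of entries dropped out
sim = zifa.simulate_factor_data(seed=11)
print("dropout rate:", round(sim.dropout_rate, 3))

state = zifa.fit_exact(sim.Y, K=10, seed=11)
print("converged:", state.converged, "iterations:", state.iteration)
print("fitted lam:", round(state.params.lam, 4))

for name, Z in [
    ("zifa", state.Z_hat),
    ("pca", zifa.fit_pca(sim.Y, 10).Z_hat),
    ("ppca", zifa.fit_ppca(sim.Y, 10).Z_hat),
    ("fa", zifa.fit_fa(sim.Y, 10, seed=11).Z_hat),
]:
    score = zifa.distance_recovery_score(sim.truth.Z, Z)
    print(f"{name:5s} spearman:", round(score.spearman, 3))
```

prints

```
dropout rate: 0.431
converged: True iterations: 110
fitted lam: 0.0996
zifa  spearman: 0.806
pca   spearman: 0.658
ppca  spearman: 0.65
fa    spearman: 0.647
```

The fitted decay parameter lands on the generating value (0.1), and the
Spearman correlation between true and estimated cell–cell distance
matrices — the rotation-proof measure of how well the embedding recovers
the latent geometry — is markedly higher for the dropout-aware model than
for PCA/PPCA/FA on the same data.

The same functionality is available from the shell:

```sh
zifa simulate --preset base --seed 11 --out sim/
zifa fit --input sim/Y.csv --k 10 --mode block --block-size 50 \
         --seed 11 --out params.json --latent Z.csv
```

`--mode exact` performs the joint E-step over all genes; the default
block mode partitions genes into blocks (exact within each block,
precision-weighted pooling of the latent posteriors across blocks) and
scales linearly with gene count.

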