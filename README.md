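# jobsbayes

Joint Bayesian estimation of **gene** and **spatial-cell** covariance for
matrix-variate spatial transcriptomic data.

## The problem

Spatial transcriptomic platforms (STARmap, 10x Visium, and relatives)
measure the expression of p genes in n single cells *together with* the
cells' spatial coordinates. The resulting genes × cells matrix Y is
doubly dependent: genes co-express (rows are correlated) and nearby cells
resemble each other (columns are correlated). Most spatial-clustering
pipelines reduce dimension first and discard the gene dependence; most
spatial covariance estimators treat genes one at a time and discard it too.
This package estimates both covariances jointly, and turns the estimates
into the downstream products practitioners actually use: de-noised
(smoothed) expression surfaces, spatial clusters, and a sparse gene
co-expression network.

## The model

Y follows a centered matrix-normal distribution,

    Y ~ MN_{p,n}(0, Λ, Σ),

with Λ (p × p) the gene covariance and Σ (n × n) the spatial covariance
over cell locations s_1..s_n — equivalently vec(Y) ~ N(0, Σ ⊗ Λ). For
large n, Σ is never formed. Its precision is parameterized by a modified
Cholesky factorization Σ⁻¹ = U D⁻¹ Uᵀ, made sparse by a Vecchia-type
ordered conditional independence assumption: cells are arranged in a
**maximin ordering** and each ordered cell conditions only on its
m nearest already-ordered neighbors g_m(i). Column i of U then holds
regression coefficients u_i,

    y_i | y_{g_m(i)} ~ N_p(X_i u_i, d_i Λ),

so the whole likelihood is a cascade of small multivariate regressions.
Conjugate shrinkage priors complete the model:

    u_i | d_i ~ N(0, d_i V_i),  d_i ~ IG(α_i, β_i),  Λ ~ IW(ν, Ψ),

with (α_i, β_i, V_i) tied to a three-dimensional hyperparameter
θ = (θ1, θ2, θ3) — marginal-variance-, range- and smoothness-like —
through a Matérn-inspired decay map (α_i = 6,
β_i = 5 θ1 (1 − e^{−θ2 i^{−1/p}}), V_i diagonal with geometrically
decaying entries e^{−θ3 j}). Inference is Metropolis-within-blocked-Gibbs:
exact Normal–Inverse-Gamma draws for every (u_i, d_i), an inverse-Wishart
draw for Λ, and a random-walk Metropolis step for θ against the marginal
likelihood with (u, d) integrated out in closed form. A hierarchical
variant shares (Λ, θ) across R independent tissue samples with
sample-specific spatial factors — different cells and locations per
sample, one gene network.

Because (cΛ, Σ/c) gives the same likelihood for any c > 0, all reported
summaries are **correlation** matrices.

## Worked example

```python
import jobsbayes as jb

# simulate one tissue sample with known truth: 4 genes with AR(1)
# correlation 0.7, 300 cells with an exponential spatial kernel
samples, truth = jb.simulate_dataset(jb.Scenario(p=4, n=300), seed=42)

model = jb.SpatialCovarianceModel(samples[0])
res = model.fit(m=10, n_iter=1000, n_burn=500, thin=5, seed=42)
print(res.summary())
```

```
Joint Bayesian covariance estimation (matrix-normal, Vecchia factors)
======================================================================
genes (p):            4
tissue samples (R):   1
cells per sample:     300
neighbor cap m:       10
kept draws:           100 (of 1000, burn 500, thin 5)
theta acceptance:     0.311
seed:                 42
----------------------------------------------------------------------
posterior theta (mean +/- sd):
  theta1 (variance):  2.5785 +/- 0.8187
  theta2 (range):     0.5076 +/- 0.2011
  theta3 (smoothness):0.7935 +/- 0.0377
strongest gene correlations:
  g1 ~ g2: +0.734
  g3 ~ g4: +0.668
  g2 ~ g3: +0.583
  g1 ~ g3: +0.455
  g2 ~ g4: +0.322
```

The posterior gene correlation tracks the AR(1) truth
(true first-off-diagonal 0.7, estimated 0.73/0.58/0.67):

```python
>>> res.gene_correlation().round(3)
[[1.     0.734  0.455  0.174]
 [0.734  1.     0.583  0.322]
 [0.455  0.583  1.     0.668]
 [0.174  0.322  0.668  1.   ]]
```

Downstream, the fitted neighbor regressions give a de-noised expression
surface, here correlating 0.949 with the observed data (MSE 0.089):

```python
from jobsbayes import smooth_expression, cluster_cells, decorrelate, gene_network
from jobsbayes.data import center_genes

sm = smooth_expression(center_genes(samples[0]), res)
print(sm.mean_corr, sm.mean_mse)        # 0.949  0.089
cl = cluster_cells(sm.fitted.T, range(1, 8))          # GMM, K by BIC
net = gene_network(decorrelate(samples[0].expr[:, res.orders[0].perm],
                               res.mean_factors(0)))  # graphical lasso
```

The same pipeline is available from the shell: `jobs fit`, `jobs
fit-multi`, `jobs smooth`, `jobs cluster`, `jobs network`, `jobs simulate`
(see `jobs --help`).

## Layout

- `src/jobsbayes/data.py` — containers, CSV/MTX readers, QC filtering,
  log-normalization, posterior archives
- `src/jobsbayes/ordering.py` — maximin ordering, predecessor neighbor sets
- `src/jobsbayes/core.py` — matrix-normal density, sparse Cholesky factors,
  the θ → prior map
- `src/jobsbayes/sampler.py` — conjugate updates and the blocked sampler
- `src/jobsbayes/model.py` — `SpatialCovarianceModel` / `MultiSampleModel`
  and the `PosteriorDraws` results object
- `src/jobsbayes/downstream.py` — correlation summaries, smoothing,
  GMM/BIC clustering, ARI, decorrelation, graphical-lasso network
- `src/jobsbayes/simulate.py` — synthetic data with known truth, metrics,
  recovery experiments
- `docs/methods.md` — modeling assumptions, defaults, and limitations
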