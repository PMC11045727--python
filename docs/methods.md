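# Methods

This note documents the model implemented in `jobsbayes`, the numerical
and design choices behind it, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## Model

The expression matrix Y (p genes × n cells) is modeled as a centered
matrix-normal, Y ~ MN_{p,n}(0, Λ, Σ): vec(Y) is Gaussian with covariance
Σ ⊗ Λ, where Λ captures gene co-expression and Σ spatial dependence
between cells. Centering is a modeling assumption, not a property of real
data — each gene is mean-centered across cells before fitting (the
`center=True` default), so fitted values and smoothed surfaces live on the
centered scale.

The two covariances are only identified up to a scale swap: (cΛ, Σ/c)
yields the same distribution for every c > 0. All user-facing summaries
are therefore correlation matrices; raw posterior draws of Λ and the
(u, d) factors are available but their absolute scales are not separately
meaningful.

### Sparse spatial precision

Σ⁻¹ is parameterized by the modified Cholesky factorization
Σ⁻¹ = U D⁻¹ Uᵀ with U unit upper triangular and D = diag(d_1..d_n) > 0.
Cells are arranged in a maximin ordering (each successive location
maximizes its minimum distance to the locations already placed; the seed
point is the one nearest the coordinate centroid, which makes the ordering
deterministic). Ordered conditional independence restricts each cell's
conditional to its min(m, i−1) nearest ordered predecessors g_m(i), so U
has at most m off-diagonal nonzeros per column and the likelihood
factorizes into n small regressions

    y_i | y_{g_m(i)} ~ N_p(X_i u_i, d_i Λ),

where X_i collects the neighbor columns sorted by increasing distance.
Sign convention: u_i are regression coefficients (conditional mean
X_i u_i) and U[g_m(i), i] = −u_i; this is verified against dense inverses
in the test suite. At m = n−1 the factorization is exact for any SPD Σ;
for smaller m the KL gap to the dense model shrinks as m grows (tested
empirically on small instances).

The exact O(n²) maximin algorithm is used; the package targets desk-scale
problems of up to a few thousand cells per sample. Duplicate coordinates
(common in gridded platforms after rounding) are deterministically
jittered by 1e-6 of the coordinate range so that distances, and hence the
ordering, are well defined.

### Priors and the hyperparameter map

Conjugate shrinkage priors are placed per column, tied together by a
three-dimensional hyperparameter θ = (θ1, θ2, θ3), all positive:

    α_i = 6
    β_i = 5 θ1 (1 − exp(−θ2 · i^{−1/p}))
    V_i = diag(v_i1..v_im_i),  v_ij = exp(−θ3 j) / (θ1 (1 − exp(−θ2 · i^{−1/p})))

with u_i | d_i ~ N(0, d_i V_i) and d_i ~ IG(α_i, β_i). The decay over the
order position i mimics how conditional variances of a Matérn-type field
fall along a maximin ordering: θ1 acts like a marginal variance, θ2 like a
range, θ3 like a smoothness (far neighbors, larger j, are shrunk
hardest). Two readings of the exponent are defensible — gene count p or
spatial dimension d — and both are implemented
(`RunConfig.decay_exponent`, default `"genes"` = i^{−1/p}); the neighbor
index j counts neighbors by increasing distance. θ gets a flat prior and
is sampled on the log scale to enforce positivity.

The gene covariance carries Λ ~ IW(ν, Ψ) with defaults ν = p + 2 (proper,
weakly informative) and Ψ = I, both configurable.

### Sampler

One sweep of the Metropolis-within-blocked-Gibbs sampler:

1. **(u_i, d_i) block.** Exact Normal–Inverse-Gamma conjugate draws per
   column: V*_i = (V_i⁻¹ + X_iᵀΛ⁻¹X_i)⁻¹, μ*_i = V*_i X_iᵀΛ⁻¹y_i,
   d_i ~ IG(α_i + p/2, β_i + (y_iᵀΛ⁻¹y_i − μ*ᵀV*⁻¹μ*)/2),
   u_i | d_i ~ N(μ*_i, d_i V*_i).
2. **Λ.** Inverse-Wishart full conditional
   IW(ν + Σ_r n_r, Ψ + Σ_r Σ_i e_ri e_riᵀ / d_ri) on the residuals
   e_i = y_i − X_i u_i, pooled over tissue samples.
3. **θ.** Joint random-walk Metropolis on (log θ1, log θ2, log θ3)
   against the marginal likelihood with (u, d) integrated out
   analytically (a product of multivariate-t evidences, computed fully in
   log space). Marginalizing (u, d) while conditioning on Λ is valid as a
   partially collapsed step because the next sweep re-draws (u, d) from
   their full conditional before Λ is updated again.

Λ⁻¹ is only ever applied through Cholesky solves of a whitened data copy
W = L⁻¹Y; no explicit inverses are formed. All columns beyond position m
share the neighbor-set size m, so their m×m factorizations run as stacked
(batched) array operations; the cached Gram statistics depend only on Λ
and are shared between the (u, d) block and the two θ-marginal
evaluations of each sweep. A proposal that makes β_i underflow to zero
(degenerate prior) is rejected outright.

Initialization: θ = (1, 1, 1); Λ starts at the pooled sample gene
covariance shrunk 10% toward its diagonal (a data-informed start that
avoids early non-PD scale matrices). The θ proposal scale (default 0.1)
adapts by Robbins–Monro toward 0.3 acceptance during burn-in only and is
frozen afterwards to preserve detailed balance. Default chain settings are
5,000 iterations, 2,500 burn-in, thin 5; the recovery experiments shipped
with the package use 400–600 iterations with half burn-in, which the
simulations show is enough for stable correlation summaries at desk scale
(p ≤ 10, n ≤ 500) thanks to the mostly-conjugate blocking. Identical seed
and configuration reproduce traces bitwise.

### Multiple tissue samples

For R independent samples on a common gene list, each Y_r is matrix-normal
with shared Λ and sample-specific Σ_r built on its own maximin ordering;
θ is shared and updated once per sweep against the summed per-sample
marginal. Only (Λ, θ) are shared — no pooling of (u, d) across samples.
The single-sample model is literally the R = 1 case of this sampler, so
both paths consume the identical random stream. Gene lists are aligned by
intersection (`align_genes`) before fitting.

## Downstream products

- **Correlation summaries.** Gene correlation = posterior-mean Λ rescaled
  to unit diagonal; spatial correlation = inverse of the precision
  assembled from posterior-mean (u, d), rescaled. Near-PSD results are
  eigenvalue-clipped and logged.
- **Smoothing.** Fitted values ŷ_i = X_i E[u_i | data] in maximin order,
  mapped back to the original cell order (the first ordered cell has no
  predecessors and is fitted as 0 on the centered scale). This matches
  the one-directional regression structure the model was fitted with; a
  `method="full"` option computes the dense bidirectional conditional
  mean E[y_i | y_{−i}] for small n.
- **Clustering.** Full-covariance Gaussian mixtures on cells (features =
  smoothed expression), 10 restarts, fixed internal seed, K selected by
  BIC; singular components trigger a logged covariance-regularization
  fallback. Agreement with reference labels is measured by the adjusted
  Rand index.
- **Network.** Data are decorrelated as Ỹ = Y U D^{−1/2} (columns
  approximately i.i.d. N(0, Λ) under the fitted spatial model), then a
  sparse precision is estimated by graphical lasso over a penalty grid.
  Each candidate support is scored by extended BIC (γ = 0.5) with the
  likelihood evaluated at the ML precision refitted on that support via
  iterative proportional scaling — scoring the shrunken penalized
  estimate directly would systematically favor the smallest penalty and
  densest graph. Node degrees identify hub genes.

## Synthetic data

The generator draws cell locations uniformly on the unit square (or
cube), builds Σ from a Matérn kernel (variance, length scale, smoothness;
smoothness 0.5 = exponential kernel; 1e-8 diagonal jitter), and a
structured Λ: AR(1) with parameter ρ, banded Toeplitz, the inverse of a
path-graph (tridiagonal) precision, or identity. Defaults emulate the
regimes the model is designed for — a modest gene panel (p = 5) with
strong co-expression (ρ = 0.7) over hundreds of cells (n = 150–400) with
exponential-kernel spatial dependence of range 0.3 on the unit square.

Heavy-tailed sensitivity data come from a matrix-variate t: the row
covariance is mixed as W ~ IW(df + p − 1, df·Λ) and Y | W ~ MN(0, W, Σ).
This keeps the stated moments (entry variance Λ_ii Σ_jj df/(df−2), excess
kurtosis at small df, matrix-normal limit as df → ∞) while genuinely
perturbing the realized gene covariance — a single scalar mixing variable
would only rescale the matrix, which correlation-scale estimation is
invariant to, making the degrees of freedom irrelevant by construction.

What the generator does **not** emulate: count noise (expression is
Gaussian, not negative-binomial counts), zero inflation/dropout, tissue
anatomy (locations are uniform, not arranged in layers or domains),
platform effects between samples, and mean structure (fields are
mean-zero). Passing recovery tests therefore demonstrates correctness of
the estimator under its own assumptions and robustness to elliptical tail
misspecification — not performance on raw counts, which should be
QC-filtered, log-normalized (`qc_filter_cells`, `log_normalize`) and
inspected before fitting.

Evaluation metrics: Gaussian KL divergence
0.5[tr(Σ_est⁻¹Σ_true) − n + log|Σ_est| − log|Σ_true|] (reported raw and on
the log scale) and relative Frobenius error ‖est − true‖_F/‖true‖_F, both
computed on correlation matrices to respect the scale non-identifiability.
The gene-independence baseline is the same sampler with Λ frozen at the
identity, which isolates exactly the contribution of modeling gene
dependence.

## Numerical choices and degenerate inputs

- All SPD checks go through Cholesky; failures raise with a
  condition-number report rather than silently regularizing.
- QC filtering removes cells with total counts outside
  median ± k·MAD (default k = 3); a zero MAD (all totals equal) removes
  nothing, and removing every cell is an error. "Extreme expression" has
  no canonical definition, so the rule and threshold are configurable.
- Log-normalization scales each cell to the median total before log1p; a
  zero-total cell is an error naming the cell.
- Ties in the maximin ordering and in neighbor distances break toward the
  lowest index (stable sorts), keeping results deterministic.
- The IG draw uses d = β*/Gamma(α*); the IW draw is delegated to scipy.

## Limitations

- O(n²) ordering and O(n³) dense inversion for materialized spatial
  correlation matrices cap practical sample sizes at a few thousand cells.
- The θ map ties all columns to three global hyperparameters; strongly
  nonstationary tissues violate this.
- Smoothing is in-sample conditional means; no prediction at unobserved
  locations beyond the neighbor structure.
- Inference is MCMC only; no variational approximation is provided.
- Spatially-variable-gene selection is out of scope: the package expects
  a pre-selected gene panel.
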