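"""Downstream products: correlation summaries, expression smoothing, spatial
clustering, and the gene co-expression network.

The pipeline mirrors the analysis a user runs after fitting: take the
posterior estimates of the gene and spatial correlations, smooth the
expression surface through the fitted neighbor regressions, cluster cells on
the smoothed expression with a Gaussian mixture (K chosen by BIC), and
estimate a sparse gene network by graphical lasso on spatially decorrelated
data.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import scipy.linalg
import scipy.sparse
from sklearn.covariance import graphical_lasso
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from .core import CholeskyFactors, factors_to_correlation
from .data import SpatialExpression
from .model import PosteriorDraws

logger = logging.getLogger("jobsbayes")


@dataclasses.dataclass
class CorrelationSummary:
    gene_corr: np.ndarray  # p x p, unit diagonal
    spatial_corr: list[np.ndarray] | None  # per sample, in maximin order


@dataclasses.dataclass
class SmoothResult:
    fitted: np.ndarray  # p x n, original cell order
    per_gene_corr: np.ndarray
    per_gene_mse: np.ndarray

    @property
    def mean_corr(self) -> float:
        return float(np.nanmean(self.per_gene_corr))

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.per_gene_mse))


@dataclasses.dataclass
class ClusterResult:
    labels: np.ndarray  # 1..K per cell
    k: int
    bic_trace: dict[int, float]


@dataclasses.dataclass
class NetworkResult:
    precision: np.ndarray
    adjacency: np.ndarray  # boolean, zero diagonal
    penalty: float
    degrees: np.ndarray
    ebic_trace: dict[float, float]

    def hub_genes(self, genes: list[str], top: int = 5) -> list[tuple[str, int]]:
        order = np.argsort(-self.degrees)[:top]
        return [(genes[i], int(self.degrees[i])) for i in order]


def _psd_project(mat: np.ndarray, tol: float = -1e-8) -> np.ndarray:
    w, v = np.linalg.eigh(mat)
    if w.min() >= tol:
        return mat
    logger.info("projecting correlation summary to PSD (min eig %.2e)", w.min())
    w = np.clip(w, 0.0, None)
    out = (v * w) @ v.T
    s = np.sqrt(np.diag(out))
    out = out / np.outer(s, s)
    np.fill_diagonal(out, 1.0)
    return 0.5 * (out + out.T)


def summarize_correlations(
    draws: PosteriorDraws, materialize_spatial: bool = True
) -> CorrelationSummary:
    """Posterior gene correlation and per-sample spatial correlations.

    The gene correlation is the posterior-mean Lambda rescaled to unit
    diagonal; spatial correlations come from the posterior-mean Cholesky
    factors via the assembled precision.  Set ``materialize_spatial=False``
    to skip the n x n matrices for large samples.
    """
    if draws.n_draws < 1:
        raise ValueError("no stored draws")
    gene = _psd_project(draws.gene_correlation())
    spatial = None
    if materialize_spatial:
        spatial = [
            _psd_project(factors_to_correlation(draws.mean_factors(r)))
            for r in range(draws.n_samples)
        ]
    return CorrelationSummary(gene_corr=gene, spatial_corr=spatial)


def smooth_expression(
    sx: SpatialExpression,
    draws: PosteriorDraws,
    r: int = 0,
    method: str = "predecessor",
) -> SmoothResult:
    """Fitted (de-noised) expression surface from the posterior regressions.

    With ``method="predecessor"`` each ordered cell's fitted value is
    X_i E[u_i | data] — the conditional mean given its predecessor
    neighbors, exactly the structure the model was fitted with; the first
    ordered cell has no predecessors and is fitted as 0 on the centered
    scale.  ``method="full"`` instead computes the Gaussian conditional
    mean E[y_i | y_(-i)] under the posterior-mean precision (dense; small n
    only).  Fitted values are returned in the original cell order together
    with the per-gene correlation and mean squared error between observed
    and smoothed expression.
    """
    order = draws.orders[r]
    y_ord = sx.expr[:, order.perm]
    if method == "predecessor":
        u_mean = draws.u_trace[r].mean(axis=0)
        fitted_ord = np.zeros_like(y_ord)
        for i, g in enumerate(order.neighbors):
            if g.size:
                fitted_ord[:, i] = y_ord[:, g] @ u_mean[i, : g.size]
    elif method == "full":
        from .core import assemble_precision

        prec = assemble_precision(draws.mean_factors(r)).toarray()
        # E[y_i | y_-i] = y_i - (Y P)_:,i / P_ii for each gene row
        yp = y_ord @ prec
        fitted_ord = y_ord - yp / np.diag(prec)
    else:
        raise ValueError("method must be 'predecessor' or 'full'")
    fitted = np.empty_like(fitted_ord)
    fitted[:, order.perm] = fitted_ord
    obs = sx.expr
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant genes -> nan corr
        corr = np.array(
            [np.corrcoef(obs[g], fitted[g])[0, 1] for g in range(sx.p)]
        )
    mse = np.mean((obs - fitted) ** 2, axis=1)
    return SmoothResult(fitted=fitted, per_gene_corr=corr, per_gene_mse=mse)


def cluster_cells(
    features: np.ndarray, k_range=range(1, 11), seed: int = 0
) -> ClusterResult:
    """Gaussian-mixture clustering of cells with BIC model selection.

    ``features`` is cells x features (e.g. the transposed smoothed
    expression).  Full-covariance mixtures are fitted over ``k_range`` with
    10 restarts and a fixed internal seed; K minimizing BIC wins.  Labels
    are 1-based.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    features = np.asarray(features, dtype=float)
    bic: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in k_range:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=10,
            random_state=seed,
            reg_covar=1e-6,
        )
        try:
            gm.fit(features)
        except ValueError:
            logger.warning("GMM with K=%d degenerate; raising reg_covar", k)
            gm.set_params(reg_covar=1e-3)
            gm.fit(features)
        bic[k] = float(gm.bic(features))
        fits[k] = gm
    best = min(bic, key=lambda k: (bic[k], k))
    labels = fits[best].predict(features) + 1
    return ClusterResult(labels=labels, k=best, bic_trace=bic)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement: 1 = identical (up to label
    names), ~0 expected under independent random partitions."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))


def decorrelate(y_ordered: np.ndarray, cf: CholeskyFactors) -> np.ndarray:
    """Whiten columns against the estimated spatial dependence.

    Computes Y_tilde = Y U D^{-1/2}; under the model the whitened columns
    are approximately i.i.d. N_p(0, Lambda), making them suitable input for
    the graphical-lasso network step.
    """
    n = cf.n
    y_ordered = np.asarray(y_ordered, dtype=float)
    if y_ordered.shape[1] != n:
        raise ValueError("column count does not match factors")
    rows, cols, vals = [], [], []
    for i in range(n):
        rows.append(i)
        cols.append(i)
        vals.append(1.0)
        g = cf.order.neighbors[i]
        rows.extend(g.tolist())
        cols.extend([i] * g.size)
        vals.extend((-np.asarray(cf.u[i])).tolist())
    u_mat = scipy.sparse.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return (u_mat.T @ y_ordered.T).T / np.sqrt(cf.d)


def _constrained_ml_precision(
    s: np.ndarray, adjacency: np.ndarray, max_iter: int = 200, tol: float = 1e-8
) -> np.ndarray:
    """Gaussian ML precision restricted to a given edge pattern.

    Iterative proportional scaling over the edges of the graph: each pass
    matches the implied pairwise covariance of every allowed edge (and every
    diagonal) to the sample covariance while keeping forbidden entries of
    the precision at zero.
    """
    p = s.shape[0]
    prec = np.diag(1.0 / np.diag(s))
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p) if adjacency[i, j]]
    for _ in range(max_iter):
        delta = 0.0
        cov = np.linalg.inv(prec)
        for c in [(i,) for i in range(p)] + pairs:
            idx = np.ix_(c, c)
            update = np.linalg.inv(s[idx]) - np.linalg.inv(cov[idx])
            prec_new = prec.copy()
            prec_new[idx] += update
            delta = max(delta, np.abs(update).max())
            prec = prec_new
            cov = np.linalg.inv(prec)
        if delta < tol:
            break
    return 0.5 * (prec + prec.T)


def gene_network(
    y_decorrelated: np.ndarray,
    penalty_grid=None,
    ebic_gamma: float = 0.5,
) -> NetworkResult:
    """Sparse gene precision network by graphical lasso with EBIC selection.

    The sample covariance of the (decorrelated) columns is fed to graphical
    lasso over ``penalty_grid``.  Each penalty's support is scored by the
    extended BIC ``-n(logdet T - tr(ST)) + |E| log n + 4 gamma |E| log p``,
    with the likelihood evaluated at the ML precision refitted on that
    support (scoring the shrunken penalized estimate directly would always
    favor the smallest penalty).  Returns the refitted precision, the
    off-diagonal adjacency and node degrees (hubs = high-degree genes).
    """
    y = np.asarray(y_decorrelated, dtype=float)
    p, n = y.shape
    if n <= 1:
        raise ValueError("need more than one column")
    s_cov = (y @ y.T) / n
    if penalty_grid is None:
        penalty_grid = np.geomspace(0.01, 1.0, 15)
    ebic: dict[float, float] = {}
    supports: dict[float, np.ndarray] = {}
    refits: dict[float, np.ndarray] = {}
    seen: set[bytes] = set()
    for alpha in penalty_grid:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, prec = graphical_lasso(s_cov, alpha=float(alpha), max_iter=200)
        except (FloatingPointError, ValueError) as exc:
            logger.warning("graphical lasso failed at penalty %.4g: %s", alpha, exc)
            continue
        adjacency = (np.abs(prec) > 1e-8) & ~np.eye(p, dtype=bool)
        key = adjacency.tobytes()
        if key in seen:  # same support as a previous penalty: same EBIC
            continue
        seen.add(key)
        refit = _constrained_ml_precision(s_cov, adjacency)
        n_edges = int(adjacency.sum()) // 2
        sign, logdet = np.linalg.slogdet(refit)
        ll = n * (logdet - np.trace(s_cov @ refit)) if sign > 0 else -np.inf
        ebic[float(alpha)] = float(
            -ll + n_edges * np.log(n) + 4.0 * ebic_gamma * n_edges * np.log(p)
        )
        supports[float(alpha)] = adjacency
        refits[float(alpha)] = refit
    if not refits:
        raise RuntimeError("graphical lasso failed at every penalty")
    best = min(ebic, key=lambda a: (ebic[a], a))
    adjacency = supports[best]
    return NetworkResult(
        precision=refits[best],
        adjacency=adjacency,
        penalty=best,
        degrees=adjacency.sum(axis=0).astype(int),
        ebic_trace=ebic,
    )
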