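"""Model and Results objects for joint gene/spatial covariance estimation.

``SpatialCovarianceModel`` holds one preprocessed tissue sample (genes x
cells expression plus cell coordinates); ``fit()`` runs the
Metropolis-within-blocked-Gibbs sampler and returns a ``PosteriorDraws``
results object carrying the MCMC traces, posterior summaries and
diagnostics.  ``MultiSampleModel`` is the hierarchical extension: R
independent tissue samples on a common gene list share the gene covariance
Lambda and the prior hyperparameters theta while keeping sample-specific
spatial factors.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from . import sampler as _sampler
from .core import CholeskyFactors, GenePrior, factors_to_correlation
from .data import RunConfig, SpatialExpression, center_genes, dedupe_coords
from .ordering import MaximinOrder, build_order


def _to_correlation(mat: np.ndarray) -> np.ndarray:
    s = np.sqrt(np.diag(mat))
    corr = mat / np.outer(s, s)
    corr = 0.5 * (corr + corr.T)
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclasses.dataclass
class PosteriorDraws:
    """Thinned post-burn-in MCMC traces plus enough metadata to reuse them.

    ``lam_trace`` is K x p x p, ``theta_trace`` K x 3; ``u_trace[r]`` is
    K x n_r x m (zero-padded to the neighbor cap) and ``d_trace[r]`` is
    K x n_r for tissue sample r.
    """

    lam_trace: np.ndarray
    theta_trace: np.ndarray
    u_trace: list[np.ndarray]
    d_trace: list[np.ndarray]
    orders: list[MaximinOrder]
    config: RunConfig
    seed: int
    acceptance_rate: float
    samples_meta: list[dict]
    genes: list[str] | None = None
    data: list[SpatialExpression] | None = None  # centered, original cell order

    # -- basic properties -------------------------------------------------
    @property
    def n_draws(self) -> int:
        return self.lam_trace.shape[0]

    @property
    def p(self) -> int:
        return self.lam_trace.shape[1]

    @property
    def n_samples(self) -> int:
        return len(self.d_trace)

    # -- posterior summaries ---------------------------------------------
    def posterior_mean_lambda(self) -> np.ndarray:
        return self.lam_trace.mean(axis=0)

    def gene_correlation(self) -> np.ndarray:
        """Posterior-mean gene covariance rescaled to a correlation matrix.

        Correlations are the reportable scale: the matrix-normal likelihood
        only identifies Lambda and Sigma up to a swap of scale (c*Lambda,
        Sigma/c).
        """
        return _to_correlation(self.posterior_mean_lambda())

    def posterior_mean_theta(self) -> np.ndarray:
        return self.theta_trace.mean(axis=0)

    def mean_factors(self, r: int = 0) -> CholeskyFactors:
        """Posterior-mean (u, d) factors for tissue sample r."""
        order = self.orders[r]
        u_mean = self.u_trace[r].mean(axis=0)
        d_mean = self.d_trace[r].mean(axis=0)
        u = [u_mean[i, : g.size] for i, g in enumerate(order.neighbors)]
        return CholeskyFactors(u=u, d=d_mean, order=order)

    def spatial_correlation(self, r: int = 0) -> np.ndarray:
        """Spatial (cell-cell) correlation implied by the posterior-mean
        factors of sample r, in maximin order."""
        return factors_to_correlation(self.mean_factors(r))

    def summary(self) -> str:
        theta_mean = self.posterior_mean_theta()
        theta_sd = self.theta_trace.std(axis=0)
        lines = [
            "Joint Bayesian covariance estimation (matrix-normal, Vecchia factors)",
            "=" * 70,
            f"genes (p):            {self.p}",
            f"tissue samples (R):   {self.n_samples}",
            "cells per sample:     "
            + ", ".join(str(m["n"]) for m in self.samples_meta),
            f"neighbor cap m:       {self.config.m}",
            f"kept draws:           {self.n_draws} "
            f"(of {self.config.n_iter}, burn {self.config.n_burn}, thin {self.config.thin})",
            f"theta acceptance:     {self.acceptance_rate:.3f}",
            f"seed:                 {self.seed}",
            "-" * 70,
            "posterior theta (mean +/- sd):",
            f"  theta1 (variance):  {theta_mean[0]:.4f} +/- {theta_sd[0]:.4f}",
            f"  theta2 (range):     {theta_mean[1]:.4f} +/- {theta_sd[1]:.4f}",
            f"  theta3 (smoothness):{theta_mean[2]:.4f} +/- {theta_sd[2]:.4f}",
        ]
        corr = self.gene_correlation()
        if self.p > 1:
            iu = np.triu_indices(self.p, 1)
            top = np.argsort(-np.abs(corr[iu]))[:5]
            lines.append("strongest gene correlations:")
            names = self.genes or [f"g{i + 1}" for i in range(self.p)]
            for t in top:
                a, b = iu[0][t], iu[1][t]
                lines.append(f"  {names[a]} ~ {names[b]}: {corr[a, b]:+.3f}")
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------
    def trace_arrays(self) -> dict[str, np.ndarray]:
        out = {"lam": self.lam_trace, "theta": self.theta_trace}
        for r in range(self.n_samples):
            o = self.orders[r]
            pad = np.full((o.n, self.config.m), -1, dtype=np.int64)
            for i, g in enumerate(o.neighbors):
                pad[i, : g.size] = g
            out[f"u{r}"] = self.u_trace[r]
            out[f"d{r}"] = self.d_trace[r]
            out[f"perm{r}"] = o.perm
            out[f"nbrs{r}"] = pad
            out[f"minstep{r}"] = o.minstep
        return out

    @classmethod
    def from_arrays(cls, arrays, config, seed, acceptance_rate, samples_meta):
        n_samples = len(samples_meta)
        orders, u_tr, d_tr = [], [], []
        for r in range(n_samples):
            pad = arrays[f"nbrs{r}"]
            neighbors = [row[row >= 0].astype(np.int64) for row in pad]
            orders.append(
                MaximinOrder(
                    perm=arrays[f"perm{r}"].astype(np.int64),
                    neighbors=neighbors,
                    m=config.m,
                    minstep=arrays[f"minstep{r}"],
                )
            )
            u_tr.append(arrays[f"u{r}"])
            d_tr.append(arrays[f"d{r}"])
        return cls(
            lam_trace=arrays["lam"],
            theta_trace=arrays["theta"],
            u_trace=u_tr,
            d_trace=d_tr,
            orders=orders,
            config=config,
            seed=seed,
            acceptance_rate=acceptance_rate,
            samples_meta=samples_meta,
        )

    def save(self, path) -> None:
        from .data import save_posterior

        save_posterior(self, path)


class MultiSampleModel:
    """Hierarchical model for R tissue samples sharing (Lambda, theta).

    Parameters
    ----------
    samples : sequence of SpatialExpression
        Samples on an identical gene list (use :func:`align_genes` first if
        they differ).  Coordinates are independent per sample.
    center : bool
        Center each gene within each sample before fitting (the model is
        mean-zero); default True.
    """

    def __init__(self, samples: Sequence[SpatialExpression], center: bool = True):
        samples = list(samples)
        if not samples:
            raise ValueError("need at least one sample")
        genes0 = samples[0].genes
        for sx in samples[1:]:
            if sx.genes != genes0:
                raise ValueError(
                    "gene lists differ between samples; run align_genes() first"
                )
        self.genes = list(genes0)
        self.p = samples[0].p
        self.samples = [center_genes(sx) if center else sx.copy() for sx in samples]

    @classmethod
    def from_dataframes(cls, pairs, center: bool = True) -> "MultiSampleModel":
        """Build from (expression DataFrame, coordinate DataFrame) pairs.

        Expression frames are genes x cells with gene identifiers in the
        index; coordinate frames need columns x,y[,z] in cell order.
        """
        sxs = []
        for k, (edf, cdf) in enumerate(pairs):
            axis_cols = [c for c in ("x", "y", "z") if c in cdf.columns]
            sxs.append(
                SpatialExpression(
                    edf.to_numpy(dtype=float),
                    [str(g) for g in edf.index],
                    cdf[axis_cols].to_numpy(dtype=float),
                    sample_id=f"sample{k + 1}",
                )
            )
        return cls(sxs, center=center)

    def fit(
        self,
        config: RunConfig | None = None,
        fix_lambda: np.ndarray | None = None,
        **kwargs,
    ) -> PosteriorDraws:
        """Run the sampler; keyword arguments override RunConfig fields."""
        cfg = config or RunConfig()
        if kwargs:
            d = cfg.to_dict()
            d.update(kwargs)
            cfg = RunConfig.from_dict(d)
        rng = np.random.default_rng(cfg.seed)
        p = self.p
        nu = cfg.nu if cfg.nu is not None else p + 2
        prior = GenePrior(nu=nu, psi=cfg.psi_scale * np.eye(p))

        orders, sdata = [], []
        for sx in self.samples:
            coords = (
                dedupe_coords(sx.coords, seed=cfg.seed)
                if cfg.jitter_duplicates
                else sx.coords
            )
            o = build_order(coords, cfg.m)
            orders.append(o)
            sdata.append(_sampler._SampleData(sx.expr[:, o.perm], o))

        # data-informed start: pooled gene covariance shrunk toward its diagonal
        pooled = np.hstack([sx.expr for sx in self.samples])
        s = np.cov(pooled) if p > 1 else np.atleast_2d(np.var(pooled))
        s = np.atleast_2d(s)
        lam_init = 0.9 * s + 0.1 * np.diag(np.diag(s)) + 1e-6 * np.eye(p)

        exponent_base = p if cfg.decay_exponent == "genes" else self.samples[0].d
        out = _sampler.run_sampler(
            sdata,
            p,
            prior,
            cfg,
            rng,
            lam_init=lam_init,
            fix_lambda=fix_lambda,
            exponent_base=exponent_base,
        )
        meta = [
            {"sample_id": sx.sample_id, "n": sx.n, "m": cfg.m}
            for sx in self.samples
        ]
        return PosteriorDraws(
            lam_trace=out.lam,
            theta_trace=out.theta,
            u_trace=out.u,
            d_trace=out.d,
            orders=orders,
            config=cfg,
            seed=cfg.seed,
            acceptance_rate=out.acceptance_rate,
            samples_meta=meta,
            genes=self.genes,
            data=self.samples,
        )


class SpatialCovarianceModel(MultiSampleModel):
    """Single-tissue-sample model: the R = 1 case of the hierarchy.

    Example
    -------
    >>> model = SpatialCovarianceModel(sx)
    >>> res = model.fit(m=10, n_iter=2000, n_burn=1000, seed=1)
    >>> print(res.summary())
    """

    def __init__(self, sx: SpatialExpression, center: bool = True):
        super().__init__([sx], center=center)

    @classmethod
    def from_dataframe(
        cls, expr: pd.DataFrame, coords: pd.DataFrame, center: bool = True
    ) -> "SpatialCovarianceModel":
        m = MultiSampleModel.from_dataframes([(expr, coords)], center=center)
        obj = cls.__new__(cls)
        obj.__dict__.update(m.__dict__)
        return obj


def align_genes(samples: Sequence[SpatialExpression]):
    """Intersect gene lists across samples and reorder rows consistently.

    Returns ``(aligned_samples, dropped)`` where ``dropped`` maps sample_id
    to the genes that were not shared.  The common genes keep the order of
    the first sample.  Raises if the intersection is empty.
    """
    samples = list(samples)
    common = set(samples[0].genes)
    for sx in samples[1:]:
        common &= set(sx.genes)
    if not common:
        raise ValueError("no genes shared across samples")
    ordered = [g for g in samples[0].genes if g in common]
    aligned, dropped = [], {}
    for sx in samples:
        idx = [sx.genes.index(g) for g in ordered]
        dropped[sx.sample_id] = [g for g in sx.genes if g not in common]
        aligned.append(
            SpatialExpression(sx.expr[idx], ordered, sx.coords, sx.sample_id)
        )
    return aligned, dropped
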