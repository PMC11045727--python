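"""Containers, readers and preprocessing for spatial expression data.

A single tissue sample is a genes x cells expression matrix together with
the spatial coordinates of the cells.  Supported on-disk layouts are a dense
CSV/TSV (rows = genes, header row of cell identifiers, first column gene
identifiers) and Matrix Market triplets accompanied by ``genes.tsv`` /
``barcodes.tsv`` index files; coordinates come as a CSV with columns
``cell_id,x,y[,z]``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

logger = logging.getLogger("jobsbayes")

_SCHEMA_VERSION = 1


@dataclasses.dataclass
class SpatialExpression:
    """One tissue sample: expression matrix plus cell coordinates.

    Attributes
    ----------
    expr : ndarray, shape (p, n)
        Expression of p genes over n cells (columns follow ``coords`` rows).
    genes : list of str
        Gene identifiers, one per row of ``expr``.
    coords : ndarray, shape (n, d)
        Spatial coordinates of the cells, d = 2 or 3, in platform units.
    sample_id : str
        Label for the tissue sample.
    """

    expr: np.ndarray
    genes: list[str]
    coords: np.ndarray
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.genes = list(self.genes)
        if self.expr.ndim != 2:
            raise ValueError("expr must be 2-D (genes x cells)")
        p, n = self.expr.shape
        if p < 1 or n < 2:
            raise ValueError(f"need p >= 1 genes and n >= 2 cells, got p={p}, n={n}")
        if len(self.genes) != p:
            raise ValueError(f"{len(self.genes)} gene labels for {p} rows")
        if self.coords.ndim != 2 or self.coords.shape[0] != n:
            raise ValueError(
                f"coords has {self.coords.shape[0] if self.coords.ndim == 2 else '?'} "
                f"rows for {n} cells"
            )
        if self.coords.shape[1] not in (2, 3):
            raise ValueError("coords must have 2 or 3 columns")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if np.isnan(self.expr).any():
            raise ValueError("expr contains missing values")

    @property
    def p(self) -> int:
        return self.expr.shape[0]

    @property
    def n(self) -> int:
        return self.expr.shape[1]

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    def copy(self) -> "SpatialExpression":
        return SpatialExpression(
            self.expr.copy(), list(self.genes), self.coords.copy(), self.sample_id
        )


@dataclasses.dataclass
class RunConfig:
    """Sampler and preprocessing settings for one fit."""

    m: int = 10
    n_iter: int = 5000
    n_burn: int = 2500
    thin: int = 5
    seed: int = 0
    nu: float | None = None  # default p + 2, resolved at fit time
    psi_scale: float = 1.0  # Psi = psi_scale * I
    proposal_scale: float = 0.1
    adapt_target: float = 0.3
    decay_exponent: str = "genes"  # "genes" -> i^(-1/p), "spatial" -> i^(-1/d)
    jitter_duplicates: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        for name in ("n_iter", "n_burn", "thin"):
            if getattr(self, name) < (0 if name == "n_burn" else 1):
                raise ValueError(f"{name} must be positive")
        if not self.n_burn < self.n_iter:
            raise ValueError("n_burn must be smaller than n_iter")
        if self.decay_exponent not in ("genes", "spatial"):
            raise ValueError("decay_exponent must be 'genes' or 'spatial'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# readers


def _read_dense(path_expr: Path, sep: str) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path_expr, sep=sep, index_col=0)
    try:
        expr = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric entries in {path_expr}: {exc}") from exc
    if np.isnan(expr).any():
        raise ValueError(f"missing values in {path_expr}")
    return expr, [str(g) for g in df.index], [str(c) for c in df.columns]


def _read_mtx(path_expr: Path) -> tuple[np.ndarray, list[str], list[str]]:
    mat = scipy.io.mmread(path_expr)
    expr = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    base = path_expr.parent
    genes_f, cells_f = base / "genes.tsv", base / "barcodes.tsv"
    genes = (
        genes_f.read_text().split() if genes_f.exists()
        else [f"gene{i + 1}" for i in range(expr.shape[0])]
    )
    cells = (
        cells_f.read_text().split() if cells_f.exists()
        else [f"cell{i + 1}" for i in range(expr.shape[1])]
    )
    if len(genes) != expr.shape[0]:
        raise ValueError("genes.tsv length does not match matrix rows")
    if len(cells) != expr.shape[1]:
        raise ValueError("barcodes.tsv length does not match matrix columns")
    return expr, genes, cells


def load_expression(
    path_expr: str | Path,
    path_coords: str | Path,
    format: str = "csv-dense",
    sample_id: str | None = None,
) -> SpatialExpression:
    """Load an expression matrix and its cell coordinates.

    Parameters
    ----------
    path_expr : path
        Dense CSV/TSV (genes x cells) or Matrix Market ``.mtx`` file.
    path_coords : path
        CSV with columns ``cell_id,x,y[,z]``; row order defines the cell
        order and must match the expression columns in count.
    format : {"csv-dense", "tsv-dense", "mtx-triplet"}
    """
    path_expr, path_coords = Path(path_expr), Path(path_coords)
    if not path_expr.exists():
        raise FileNotFoundError(path_expr)
    if not path_coords.exists():
        raise FileNotFoundError(path_coords)
    if format == "csv-dense":
        expr, genes, cells = _read_dense(path_expr, ",")
    elif format == "tsv-dense":
        expr, genes, cells = _read_dense(path_expr, "\t")
    elif format == "mtx-triplet":
        expr, genes, cells = _read_mtx(path_expr)
    else:
        raise ValueError(f"unknown format {format!r}")

    cdf = pd.read_csv(path_coords)
    axis_cols = [c for c in ("x", "y", "z") if c in cdf.columns]
    if len(axis_cols) < 2:
        raise ValueError("coordinate file must have columns x,y[,z]")
    coords = cdf[axis_cols].to_numpy(dtype=float)
    if coords.shape[0] != expr.shape[1]:
        raise ValueError(
            f"{coords.shape[0]} coordinate rows for {expr.shape[1]} cells"
        )
    if "cell_id" in cdf.columns:
        file_ids = [str(c) for c in cdf["cell_id"]]
        if file_ids != cells and set(file_ids) == set(cells):
            order = [file_ids.index(c) for c in cells]
            coords = coords[order]
    return SpatialExpression(
        expr, genes, coords, sample_id or path_expr.stem
    )


def save_expression(sx: SpatialExpression, path_expr: str | Path, path_coords: str | Path) -> None:
    """Write a sample back to dense CSV + coordinate CSV (inverse of loading)."""
    cells = [f"cell{i + 1}" for i in range(sx.n)]
    pd.DataFrame(sx.expr, index=sx.genes, columns=cells).to_csv(path_expr)
    cols = ["x", "y", "z"][: sx.d]
    cdf = pd.DataFrame(sx.coords, columns=cols)
    cdf.insert(0, "cell_id", cells)
    cdf.to_csv(path_coords, index=False)


# ---------------------------------------------------------------------------
# preprocessing


def qc_filter_cells(
    sx: SpatialExpression, k_mad: float = 3.0
) -> tuple[SpatialExpression, list[int]]:
    """Drop cells whose total expression is extreme.

    A cell is removed when its total count falls outside
    ``median +/- k_mad * MAD`` of the per-cell totals.  Returns the filtered
    sample and the (0-based) indices of removed cells.
    """
    if not k_mad > 0:
        raise ValueError("k_mad must be positive")
    totals = sx.expr.sum(axis=0)
    med = np.median(totals)
    mad = np.median(np.abs(totals - med))
    if mad == 0:
        keep = np.ones(sx.n, dtype=bool)  # all-equal totals: nothing is extreme
    else:
        keep = np.abs(totals - med) <= k_mad * mad
    if not keep.any():
        raise ValueError("QC filter would remove every cell")
    removed = [int(i) for i in np.flatnonzero(~keep)]
    if removed:
        logger.info("qc_filter_cells removed %d/%d cells", len(removed), sx.n)
    out = SpatialExpression(
        sx.expr[:, keep], list(sx.genes), sx.coords[keep], sx.sample_id
    )
    return out, removed


def log_normalize(sx: SpatialExpression) -> SpatialExpression:
    """Median-of-totals library-size normalization followed by log1p.

    Each cell's counts are rescaled so its total equals the median of the
    per-cell totals, then ``log1p`` is applied.
    """
    if (sx.expr < 0).any():
        raise ValueError("log_normalize expects non-negative counts")
    totals = sx.expr.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cells with zero total counts: {zero.tolist()}")
    med = np.median(totals)
    scaled = sx.expr * (med / totals)
    return SpatialExpression(np.log1p(scaled), list(sx.genes), sx.coords, sx.sample_id)


def center_genes(sx: SpatialExpression) -> SpatialExpression:
    """Subtract each gene's mean across cells (the model is mean-zero)."""
    centered = sx.expr - sx.expr.mean(axis=1, keepdims=True)
    return SpatialExpression(centered, list(sx.genes), sx.coords, sx.sample_id)


def dedupe_coords(coords: np.ndarray, seed: int = 0) -> np.ndarray:
    """Jitter exactly-duplicated coordinate rows so distances are distinct.

    Magnitude is 1e-6 of the coordinate range, drawn from a seeded uniform;
    untouched when all rows are already unique.
    """
    coords = np.asarray(coords, dtype=float)
    _, first = np.unique(coords, axis=0, return_index=True)
    if first.size == coords.shape[0]:
        return coords
    logger.warning("duplicate coordinates detected; applying deterministic jitter")
    rng = np.random.default_rng(seed)
    span = max(np.ptp(coords, axis=0).max(), 1.0)
    dup = np.ones(coords.shape[0], dtype=bool)
    dup[first] = False
    out = coords.copy()
    out[dup] += rng.uniform(-1e-6, 1e-6, size=(int(dup.sum()), coords.shape[1])) * span
    return out


# ---------------------------------------------------------------------------
# posterior archive


def save_posterior(draws, path: str | Path) -> None:
    """Persist posterior draws to an archive directory.

    Layout: ``traces.npz`` (arrays), ``config.yaml`` (run settings) and
    ``manifest.json`` (schema version, seed, config hash, trace shapes).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = draws.trace_arrays()
    np.savez(path / "traces.npz", **arrays)
    (path / "config.yaml").write_text(yaml.safe_dump(draws.config.to_dict()))
    manifest = {
        "schema_version": _SCHEMA_VERSION,
        "seed": draws.seed,
        "config_hash": draws.config.digest(),
        "acceptance_rate": draws.acceptance_rate,
        "n_samples": len(draws.samples_meta),
        "samples_meta": draws.samples_meta,
        "arrays": {k: list(v.shape) for k, v in arrays.items()},
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_posterior(path: str | Path):
    """Load an archive written by :func:`save_posterior` (lossless round trip)."""
    from .model import PosteriorDraws  # local import to avoid a cycle

    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest.json under {path}")
    manifest = json.loads(mpath.read_text())
    if manifest.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError(
            f"posterior archive schema {manifest.get('schema_version')} "
            f"!= supported {_SCHEMA_VERSION}"
        )
    config = RunConfig.from_dict(yaml.safe_load((path / "config.yaml").read_text()))
    if config.digest() != manifest["config_hash"]:
        raise ValueError("config.yaml does not match manifest hash")
    with np.load(path / "traces.npz") as npz:
        arrays = {k: npz[k] for k in npz.files}
    for key, shape in manifest["arrays"].items():
        if key not in arrays or list(arrays[key].shape) != shape:
            raise ValueError(f"trace array {key!r} missing or truncated")
    return PosteriorDraws.from_arrays(
        arrays,
        config=config,
        seed=manifest["seed"],
        acceptance_rate=manifest["acceptance_rate"],
        samples_meta=manifest["samples_meta"],
    )
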