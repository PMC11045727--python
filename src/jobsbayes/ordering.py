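"""Maximin ordering of spatial locations and predecessor conditioning sets.

The maximin ordering seeds at the point nearest the coordinate centroid and
then repeatedly appends the point whose minimum distance to the already
ordered points is largest, spreading early points over the whole domain.
Conditioning each location on its m nearest *predecessors* in this order
yields the sparse Cholesky factor of the spatial precision used throughout
the model: at most m off-diagonal nonzeros per column.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import cdist


@dataclasses.dataclass
class MaximinOrder:
    """A maximin permutation plus per-location predecessor neighbor sets.

    Attributes
    ----------
    perm : ndarray of int
        ``perm[k]`` is the original index of the k-th location in maximin
        order (0-based).
    neighbors : list of ndarray
        ``neighbors[i]`` holds the ordered-index predecessors of location i
        (all < i), sorted by increasing distance to location i; length
        ``min(m, i)``.
    m : int
        Conditioning-set size cap.
    minstep : ndarray
        Distance to the nearest already-ordered point at selection time;
        non-increasing from the second entry on.
    """

    perm: np.ndarray
    neighbors: list[np.ndarray]
    m: int
    minstep: np.ndarray

    @property
    def n(self) -> int:
        return self.perm.size

    def sizes(self) -> np.ndarray:
        return np.array([g.size for g in self.neighbors])


def maximin_order(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy exact maximin permutation of ``coords`` (O(n^2)).

    Seeds at the point nearest the centroid; each subsequent point maximizes
    its minimum Euclidean distance to all previously selected points.  Ties
    break toward the lowest original index.  Returns ``(perm, minstep)``
    where ``minstep[k]`` is the distance of the k-th selected point to its
    nearest predecessor (``inf`` for the seed).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2:
        raise ValueError("coords must be n x d")
    n = coords.shape[0]
    if n == 0:
        raise ValueError("need at least one location")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite")
    centroid = coords.mean(axis=0)
    seed = int(np.argmin(np.linalg.norm(coords - centroid, axis=1)))
    perm = np.empty(n, dtype=np.int64)
    minstep = np.empty(n)
    perm[0], minstep[0] = seed, np.inf
    # mindist[j]: distance from point j to the closest already-selected point
    mindist = np.linalg.norm(coords - coords[seed], axis=1)
    mindist[seed] = -np.inf
    for k in range(1, n):
        nxt = int(np.argmax(mindist))  # argmax takes the first max -> lowest index
        perm[k], minstep[k] = nxt, mindist[nxt]
        mindist = np.minimum(mindist, np.linalg.norm(coords - coords[nxt], axis=1))
        mindist[nxt] = -np.inf
    return perm, minstep


def predecessor_neighbors(coords_ordered: np.ndarray, m: int) -> list[np.ndarray]:
    """Nearest-predecessor conditioning sets in an already ordered layout.

    ``g[0]`` is empty; for i >= 1, ``g[i]`` is the ``min(m, i)`` predecessors
    closest to point i, sorted by increasing distance (ties toward the lower
    ordered index).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    coords_ordered = np.asarray(coords_ordered, dtype=float)
    n = coords_ordered.shape[0]
    dist = cdist(coords_ordered, coords_ordered)
    out: list[np.ndarray] = [np.empty(0, dtype=np.int64)]
    for i in range(1, n):
        k = min(m, i)
        d = dist[i, :i]
        # stable sort on distance keeps the lower index first on ties
        idx = np.argsort(d, kind="stable")[:k]
        out.append(idx.astype(np.int64))
    return out


def build_order(coords: np.ndarray, m: int) -> MaximinOrder:
    """Compute the maximin permutation and conditioning sets in one call."""
    perm, minstep = maximin_order(coords)
    nbrs = predecessor_neighbors(np.asarray(coords, dtype=float)[perm], m)
    return MaximinOrder(perm=perm, neighbors=nbrs, m=m, minstep=minstep)
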