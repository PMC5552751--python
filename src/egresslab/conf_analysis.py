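"""Conformational-state decomposition (open/closed analysis).

Frames sampled during biased runs are compared by pairwise Kabsch-aligned
RMSD on a chosen atom subset, embedded into two dimensions with classical
(Torgerson) multidimensional scaling, and clustered with DBSCAN.  The
resulting basins are summarized by occupancy fractions and medoid frames,
and external structures (e.g. crystal conformations) are assigned to the
basin of their nearest sampled frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

from .exceptions import ParameterError
from .path_cv import kabsch_align

__all__ = [
    "DistanceMatrix",
    "StateDecomposition",
    "rmsd_matrix",
    "classical_mds",
    "dbscan_cluster",
    "basin_occupancy",
    "representative_conformer",
    "assign_external",
    "suggest_eps",
    "decompose_states",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise RMSD matrix (A) with zero diagonal."""

    entries: np.ndarray
    frame_labels: list | None = None

    def __post_init__(self):
        self.entries = np.asarray(self.entries, float)
        if self.entries.ndim != 2 or self.entries.shape[0] != self.entries.shape[1]:
            raise ParameterError("distance matrix must be square")
        if not np.allclose(self.entries, self.entries.T, atol=1e-9):
            raise ParameterError("distance matrix must be symmetric")

    @property
    def size(self) -> int:
        return self.entries.shape[0]


@dataclass
class StateDecomposition:
    """2-D embedding (normalized to [0,1]^2), cluster labels (-1 = noise),
    occupancy fractions and medoid frame index per cluster."""

    embedding: np.ndarray
    labels: np.ndarray
    occupancy: dict
    medoid_index: dict


def subset_rmsd(a, b, subset) -> float:
    """Kabsch-aligned RMSD (A) between two conformations on ``subset``."""
    idx = np.asarray(subset, int)
    xa = np.asarray(getattr(a, "coordinates", a), float)
    xb = np.asarray(getattr(b, "coordinates", b), float)
    _, _, moved = kabsch_align(xa, xb, idx)
    d = moved[idx] - xb[idx]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def rmsd_matrix(confs, subset) -> DistanceMatrix:
    """All-pairs aligned RMSD over ``subset`` atoms."""
    n = len(confs)
    if n < 2:
        raise ParameterError("need at least 2 conformations")
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = subset_rmsd(confs[i], confs[j], subset)
    labels = [getattr(c, "label", str(i)) for i, c in enumerate(confs)]
    return DistanceMatrix(m, labels)


def classical_mds(dm: DistanceMatrix, dim: int = 2, normalize: bool = True) -> np.ndarray:
    """Torgerson MDS: eigendecomposition of the double-centred squared
    distance matrix, keeping the top ``dim`` eigenpairs (negative
    eigenvalues clipped to zero).

    With ``normalize=True`` each embedding axis is min--max rescaled to
    [0, 1], matching the convention in which basin centres are reported on
    a unit square; a degenerate axis maps to 0.
    """
    d = dm.entries if isinstance(dm, DistanceMatrix) else np.asarray(dm, float)
    n = d.shape[0]
    if n < 3:
        raise ParameterError("MDS needs at least 3 frames")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dim]
    lam = np.clip(vals[order], 0.0, None)
    emb = vecs[:, order] * np.sqrt(lam)
    if normalize:
        span = emb.max(axis=0) - emb.min(axis=0)
        span[span == 0] = 1.0
        emb = (emb - emb.min(axis=0)) / span
    return emb


def dbscan_cluster(embedding: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """DBSCAN labels on the embedding; noise = -1.

    ``min_pts`` counts the point itself (the classic convention).  Border
    points on the frontier of two clusters go to the cluster reached first
    in index order, as in the reference algorithm with a fixed point order.
    """
    if eps <= 0:
        raise ParameterError("eps must be positive")
    if min_pts < 1:
        raise ParameterError("min_pts must be >= 1")
    return DBSCAN(eps=eps, min_samples=min_pts).fit_predict(np.asarray(embedding, float))


def basin_occupancy(labels) -> dict:
    """Fraction of frames per cluster id, with -1 collecting the noise."""
    labels = np.asarray(labels, int)
    if labels.size == 0:
        raise ParameterError("labels are empty")
    out = {}
    for lab in np.unique(labels):
        out[int(lab)] = float(np.sum(labels == lab) / labels.size)
    return out


def representative_conformer(dm: DistanceMatrix, labels) -> dict:
    """Medoid frame per cluster: the member minimizing the summed RMSD to
    its cluster mates; ties break to the lowest frame index."""
    labels = np.asarray(labels, int)
    d = dm.entries
    out = {}
    for lab in np.unique(labels):
        if lab == -1:
            continue
        members = np.where(labels == lab)[0]
        sums = d[np.ix_(members, members)].sum(axis=1)
        out[int(lab)] = int(members[int(np.argmin(sums))])
    return out


def assign_external(conf, confs, labels, subset):
    """Assign an external structure to the basin of its nearest non-noise
    frame by subset RMSD.  Returns (label, distance)."""
    labels = np.asarray(labels, int)
    cand = np.where(labels != -1)[0]
    if cand.size == 0:
        raise ParameterError("no non-noise frames to assign against")
    dists = np.array([subset_rmsd(conf, confs[i], subset) for i in cand])
    j = int(np.argmin(dists))
    return int(labels[cand[j]]), float(dists[j])


def suggest_eps(embedding: np.ndarray, min_pts: int = 5) -> float:
    """k-distance heuristic for DBSCAN's eps: three times the median
    distance to each point's min_pts-th neighbour -- comfortably above the
    intra-basin scale but below typical basin separations."""
    from sklearn.neighbors import NearestNeighbors

    x = np.asarray(embedding, float)
    k = min(min_pts, len(x) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    dist, _ = nn.kneighbors(x)
    return float(max(3.0 * np.median(dist[:, -1]), 1e-6))


def decompose_states(confs, subset, eps: float | None = None,
                     min_pts: int = 5) -> StateDecomposition:
    """Full pipeline: pairwise RMSD -> 2-D MDS -> DBSCAN -> occupancies and
    medoids.

    Clustering runs on the raw eigenvalue-scaled embedding (min--max
    normalization would inflate near-degenerate noise axes); the reported
    embedding is normalized to the unit square, the convention basin
    centres are quoted in.  ``eps`` defaults to the k-distance suggestion,
    measured on the same raw embedding.
    """
    dm = rmsd_matrix(confs, subset)
    emb_raw = classical_mds(dm, dim=2, normalize=False)
    if eps is None:
        eps = suggest_eps(emb_raw, min_pts)
    labels = dbscan_cluster(emb_raw, eps, min_pts)
    span = emb_raw.max(axis=0) - emb_raw.min(axis=0)
    span[span == 0] = 1.0
    emb = (emb_raw - emb_raw.min(axis=0)) / span
    return StateDecomposition(emb, labels, basin_occupancy(labels),
                              representative_conformer(dm, labels))
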