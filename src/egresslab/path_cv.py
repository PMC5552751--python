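"""Path collective variables.

Progress along and deviation from a discretized reference path
S(1..N) of conformations:

    s(R) = sum_k k exp(-lambda * m_k) / sum_k exp(-lambda * m_k)
    z(R) = -(1/lambda) ln sum_k exp(-lambda * m_k)

where m_k is the mean-square deviation (A^2) between the displacement-set
atoms of the current configuration and those of node k, after rigid
superposition on the alignment set.  s runs from 1 (bound state) to N
(egress); sigma = (s-1)/(N-1) rescales it to [0, 1].  Both sums are
evaluated with the log-sum-exp trick so large lambda * MSD products never
overflow.

Because the alignment and displacement sets are disjoint, the optimal
rotation depends only on alignment atoms, and the fixed-rotation gradients
with respect to displacement atoms returned here are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import AlignmentError, ParameterError

__all__ = [
    "PCVResult",
    "kabsch_align",
    "msd_displacement",
    "pcv_msds",
    "pcv_s",
    "pcv_z",
    "pcv_eval",
    "sigma_from_s",
    "choose_lambda",
]


@dataclass
class PCVResult:
    """s, z, sigma, the per-node MSDs and (optionally) gradients of s and z
    with respect to the displacement-set coordinates."""

    s_value: float
    z_value: float
    sigma: float
    per_node_msd: np.ndarray
    grad_s: np.ndarray | None = None
    grad_z: np.ndarray | None = None


def kabsch_align(mobile, reference, alignment_set):
    """Least-squares rigid superposition (proper rotation, no reflection).

    Aligns ``mobile`` onto ``reference`` using the alignment-set atoms and
    applies the transform to every atom of ``mobile``.

    Returns ``(rotation, translation, transformed)`` such that
    ``transformed = (mobile - mob_centroid) @ rotation.T + ref_centroid``.
    """
    xm = np.asarray(getattr(mobile, "coordinates", mobile), float)
    xr = np.asarray(getattr(reference, "coordinates", reference), float)
    idx = np.asarray(alignment_set, int)
    if idx.size < 3:
        raise AlignmentError("alignment set needs at least 3 atoms")
    a = xm[idx] - xm[idx].mean(axis=0)
    b = xr[idx] - xr[idx].mean(axis=0)
    # non-collinearity: the centered set must span at least a plane
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise AlignmentError("alignment set is collinear or degenerate")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    transformed = (xm - xm[idx].mean(axis=0)) @ rot.T + xr[idx].mean(axis=0)
    trans = xr[idx].mean(axis=0) - rot @ xm[idx].mean(axis=0)
    return rot, trans, transformed


def msd_displacement(conf, node, alignment_set, displacement_set) -> float:
    """Mean-square deviation (A^2) of the displacement-set atoms after
    superposing ``conf`` onto ``node`` using the alignment set."""
    disp = np.asarray(displacement_set, int)
    _, _, moved = kabsch_align(conf, node, alignment_set)
    xr = np.asarray(getattr(node, "coordinates", node), float)
    d = moved[disp] - xr[disp]
    return float(np.mean(np.sum(d * d, axis=1)))


def pcv_msds(conf, path) -> np.ndarray:
    """Per-node MSD array m_k for a configuration against every path node."""
    return np.array([
        msd_displacement(conf, node, path.alignment_set, path.displacement_set)
        for node in path.nodes
    ])


def _weights(msds: np.ndarray, lam: float):
    if not np.all(np.isfinite(msds)):
        raise ParameterError("non-finite MSD encountered")
    a = -lam * (msds - msds.min())
    w = np.exp(a)
    return w, w.sum()


def pcv_s(conf, path, lam: float | None = None) -> float:
    """Progress variable s(R) in [1, N] (Boltzmann-weighted node index)."""
    lam = path.lambda_value if lam is None else lam
    if lam <= 0:
        raise ParameterError("lambda must be positive")
    msds = pcv_msds(conf, path)
    if msds.size < 2:
        raise ParameterError("path must have at least 2 nodes")
    w, z = _weights(msds, lam)
    k = np.arange(1, msds.size + 1)
    return float((k * w).sum() / z)


def pcv_z(conf, path, lam: float | None = None) -> float:
    """Deviation-from-path variable z(R) in A^2 (soft minimum of the MSDs)."""
    lam = path.lambda_value if lam is None else lam
    if lam <= 0:
        raise ParameterError("lambda must be positive")
    msds = pcv_msds(conf, path)
    if msds.size < 2:
        raise ParameterError("path must have at least 2 nodes")
    w, z = _weights(msds, lam)
    return float(msds.min() - np.log(z) / lam)


def pcv_eval(conf, path, lam: float | None = None,
             gradients: bool = True) -> PCVResult:
    """Evaluate s, z, sigma and, if requested, their gradients.

    Gradients are with respect to the displacement-set coordinates and are
    exact under the disjoint alignment/displacement-set convention (the
    superposition transform does not depend on displacement atoms).
    Shapes: (n_displacement, 3); units 1/A for prefactors times A, i.e.
    ds/dx in 1/A and dz/dx in A.
    """
    lam = path.lambda_value if lam is None else lam
    if lam <= 0:
        raise ParameterError("lambda must be positive")
    nodes = path.nodes
    n = len(nodes)
    if n < 2:
        raise ParameterError("path must have at least 2 nodes")
    disp = np.asarray(path.displacement_set, int)
    align = np.asarray(path.alignment_set, int)
    xm = np.asarray(getattr(conf, "coordinates", conf), float)
    # batched Kabsch against all nodes at once
    ref = np.stack([np.asarray(nd.coordinates, float) for nd in nodes])  # (N,n,3)
    a = xm[align] - xm[align].mean(axis=0)                # (na,3)
    bcent = ref[:, align].mean(axis=1, keepdims=True)
    b = ref[:, align] - bcent                             # (N,na,3)
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise AlignmentError("alignment set is collinear or degenerate")
    hmat = np.einsum("ai,kaj->kij", a, b)                 # (N,3,3)
    u, _, vt = np.linalg.svd(hmat)
    det = np.sign(np.linalg.det(np.einsum("kij,kjl->kil",
                                          vt.transpose(0, 2, 1),
                                          u.transpose(0, 2, 1))))
    corr = np.repeat(np.eye(3)[None], n, axis=0)
    corr[:, 2, 2] = det
    rots = np.einsum("kji,kjl,kml->kim", vt, corr, u)     # (N,3,3) rotation
    moved = np.einsum("kij,aj->kai", rots, xm[disp] - xm[align].mean(axis=0)) \
        + bcent                                            # (N,nd,3)
    d = moved - ref[:, disp]
    msds = np.mean(np.sum(d * d, axis=2), axis=1)
    # d m_k / d x_i = (2/n_d) R_k^T (T_k x_i - y_ki)
    dmsd = (2.0 / disp.size) * np.einsum("kai,kij->kaj", d, rots)
    w, zsum = _weights(msds, lam)
    wbar = w / zsum
    kidx = np.arange(1, n + 1)
    s = float((kidx * wbar).sum())
    zval = float(msds.min() - np.log(zsum) / lam)
    sigma = sigma_from_s(s, n)
    gs = gz = None
    if gradients:
        coef_s = -lam * wbar * (kidx - s)            # ds/dm_k
        gs = np.tensordot(coef_s, dmsd, axes=1)
        gz = np.tensordot(wbar, dmsd, axes=1)        # dz/dm_k = wbar_k
    return PCVResult(s, zval, sigma, msds, gs, gz)


def sigma_from_s(s: float, n: int) -> float:
    """Order parameter sigma = (s - 1)/(N - 1), clamped to [0, 1]."""
    if n < 2:
        raise ParameterError("N must be >= 2")
    return float(np.clip((s - 1.0) / (n - 1.0), 0.0, 1.0))


def choose_lambda(path) -> float:
    """Default lambda = 2.3 / <MSD> between consecutive nodes (A^-2).

    The standard path-CV heuristic: exp(-lambda * MSD) ~ 0.1 at one node
    spacing, so neighbouring nodes dominate the sums.  Always overridable
    by assigning ``path.lambda_value`` directly.
    """
    msd = float(path.mean_neighbor_msd)
    if msd <= 0:
        raise ParameterError("mean neighbour MSD must be positive")
    return 2.3 / msd
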