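"""Memetic-sampling search for ligand egress paths.

The reaction coordinate is assembled node by node.  Given the (k-1)th
conformation, candidate rigid-body poses of the ligand are drawn inside a
sampling sphere around the current pose and scored with the effective
ligand--environment interaction functional

    Lambda = sum_{i in ligand, j in environment} h_ij exp(-r_ij^2 / (2 w^2)) + gamma,
    h_ij = s_i v_j + s_j v_i,

where s and v are per-atom partial volumes and solvation coefficients and
gamma (optional) is the van der Waals + electrostatic interaction energy.
The best candidate is refined by a deterministic local descent on the six
rigid-body coordinates ("memetic" = population sampling + local search);
the minimizing pose becomes the target of a constant-magnitude pulling
force on the ligand COM over m Langevin steps, after which the relaxed
system snapshot is saved as node S(k).  The search terminates when the
ligand COM leaves the cage (distance >= termination_distance) or the node
budget is exhausted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from . import path_cv
from .exceptions import ConfigurationError, ParameterError
from .toysim import Conformation, System, ThermoState, langevin_step, potential_energy

__all__ = [
    "LambdaParams",
    "PathSearchConfig",
    "Pose",
    "Path",
    "lambda_energy",
    "propose_candidates",
    "memetic_minimize",
    "biased_segment",
    "build_path",
    "reparameterize_path",
]

#: Lambda values above this are treated as clashes (clamped-core energies)
CLASH_LAMBDA = 1.0e3

#: Lambda rise (kcal/mol) above the current pose that marks the outward
#: direction as pressed into the repulsive wall, triggering the
#: tangential-slide stage of the path search
PRESSED_DELTA = 10.0


@dataclass
class LambdaParams:
    """Parameters of the functional Lambda and of the candidate sampler.

    ``gaussian_width`` w defaults to 3.5 A (solvation-shell scale); the
    sampling sphere radius rho bounds each COM move and orientation
    perturbations are <= ``max_rotation`` radians.
    """

    gaussian_width: float = 3.5
    include_gamma: bool = True
    candidate_count: int = 16
    sphere_radius: float = 2.0
    local_refine_steps: int = 20
    rng_seed: int = 0
    max_rotation: float = np.deg2rad(15.0)

    def __post_init__(self):
        if self.gaussian_width <= 0:
            raise ParameterError("gaussian_width must be positive")
        if self.sphere_radius <= 0:
            raise ParameterError("sphere_radius must be positive")
        if self.candidate_count < 2:
            raise ParameterError("candidate_count must be >= 2")


@dataclass
class PathSearchConfig:
    """Biased-pulling and termination settings for the path search."""

    segment_steps: int = 100
    bias_force_magnitude: float = 6.0
    termination_distance: float = 13.0
    max_nodes: int = 100
    torque_constant: float = 2.0

    def __post_init__(self):
        if self.segment_steps < 1:
            raise ParameterError("segment_steps must be >= 1")
        if self.termination_distance <= 0:
            raise ParameterError("termination_distance must be positive")


@dataclass
class Pose:
    """Rigid-body pose: COM position plus a rotation applied to the
    body-frame (COM-centred) ligand coordinates."""

    com: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.com = np.asarray(self.com, float)
        self.rotation = np.asarray(self.rotation, float)

    def apply(self, body_coords: np.ndarray) -> np.ndarray:
        return self.com + body_coords @ self.rotation.T


@dataclass
class Path:
    """An ordered reaction coordinate S(1..N) with its CV bookkeeping."""

    nodes: list
    alignment_set: np.ndarray
    displacement_set: np.ndarray
    lambda_value: float = 0.0
    mean_neighbor_msd: float = 0.0
    complete: bool = True

    def __post_init__(self):
        self.alignment_set = np.asarray(self.alignment_set, int)
        self.displacement_set = np.asarray(self.displacement_set, int)
        if len(self.nodes) < 2:
            raise ParameterError("a path needs at least 2 nodes")
        if self.alignment_set.size == 0 or self.displacement_set.size == 0:
            raise ConfigurationError("alignment and displacement sets must be nonempty")
        if np.intersect1d(self.alignment_set, self.displacement_set).size:
            raise ConfigurationError("alignment and displacement sets must be disjoint")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def refresh_metrics(self) -> None:
        """Recompute mean neighbour MSD and the default lambda."""
        msds = [
            path_cv.msd_displacement(self.nodes[i], self.nodes[i + 1],
                                     self.alignment_set, self.displacement_set)
            for i in range(self.n_nodes - 1)
        ]
        self.mean_neighbor_msd = float(np.mean(msds))
        self.lambda_value = path_cv.choose_lambda(self)


def _ligand_com(system: System, coords: np.ndarray) -> np.ndarray:
    li = system.ligand_indices
    m = system.masses[li]
    return np.average(coords[li], axis=0, weights=m)


def lambda_energy(system: System, conf: Conformation,
                  params: LambdaParams) -> float:
    """Evaluate the functional Lambda (kcal/mol) for one conformation."""
    coords = conf.coordinates
    li, ei = system.ligand_indices, system.environment_indices
    if li.size == 0 or ei.size == 0:
        raise ConfigurationError("Lambda needs ligand and environment atoms")
    s = np.array([a.partial_volume for a in system.atoms])
    v = np.array([a.solvation_coefficient for a in system.atoms])
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(v))):
        raise ConfigurationError("partial_volume/solvation_coefficient missing")
    d = coords[li][:, None, :] - coords[ei][None, :, :]
    r2 = np.sum(d * d, axis=2)
    h = s[li][:, None] * v[ei][None, :] + s[ei][None, :] * v[li][:, None]
    total = float(np.sum(h * np.exp(-r2 / (2.0 * params.gaussian_width ** 2))))
    if params.include_gamma:
        parts = potential_energy(system, conf)
        total += parts["vdw"] + parts["coulomb"]
    return total


def propose_candidates(prev_pose: Pose, params: LambdaParams) -> list:
    """Candidate rigid-body poses inside the sampling sphere.

    Candidate 0 is ``prev_pose`` itself; the rest have COM displacements
    uniform in the ball of radius rho and orientations perturbed by a
    rotation of angle uniform in [0, max_rotation] about a uniform axis.
    Deterministic given ``params.rng_seed``.
    """
    rng = np.random.default_rng(params.rng_seed)
    out = [Pose(prev_pose.com.copy(), prev_pose.rotation.copy())]
    for _ in range(params.candidate_count - 1):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        radius = params.sphere_radius * rng.random() ** (1.0 / 3.0)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.random() * params.max_rotation
        rot = Rotation.from_rotvec(axis * angle).as_matrix()
        out.append(Pose(prev_pose.com + radius * u, rot @ prev_pose.rotation))
    return out


def _conf_with_pose(system: System, coords: np.ndarray,
                    body: np.ndarray, pose: Pose) -> Conformation:
    c = coords.copy()
    c[system.ligand_indices] = pose.apply(body)
    return Conformation(c)


def memetic_minimize(system: System, conf: Conformation, candidates: list,
                     params: LambdaParams, constraint=None):
    """Pick the Lambda-minimizing pose: best-of-candidates plus a
    coordinate-wise trust-region descent on the 6 rigid-body coordinates.

    Returns ``(pose, lambda_value, clash_flag)``; the result is never worse
    than the best raw candidate.  If every candidate sits in a clamped-core
    clash the least-bad one is returned with ``clash_flag=True``.

    ``constraint(pose) -> bool`` restricts the feasible poses (infeasible
    ones score +inf); :func:`build_path` uses it to demand monotonic
    radial progress of the ligand COM.
    """
    if not candidates:
        raise ParameterError("candidate list is empty")
    coords = conf.coordinates
    li = system.ligand_indices
    m = system.masses[li]
    com0 = np.average(coords[li], axis=0, weights=m)
    body = coords[li] - com0

    def score(pose):
        if constraint is not None and not constraint(pose):
            return np.inf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return lambda_energy(system, _conf_with_pose(system, coords, body, pose), params)

    values = [score(p) for p in candidates]
    best_i = int(np.argmin(values))
    best, best_val = candidates[best_i], values[best_i]

    step_t = 0.25 * params.sphere_radius
    step_r = np.deg2rad(5.0)
    com = best.com.copy()
    rotvec = np.zeros(3)  # incremental rotation relative to best.rotation
    base_rot = best.rotation

    def eval_at(c, rv):
        pose = Pose(c, Rotation.from_rotvec(rv).as_matrix() @ base_rot)
        return pose, score(pose)

    cur_pose, cur_val = best, best_val
    for _ in range(max(0, params.local_refine_steps)):
        improved = False
        for dim in range(6):
            for sgn in (1.0, -1.0):
                c, rv = com.copy(), rotvec.copy()
                if dim < 3:
                    c[dim] += sgn * step_t
                else:
                    rv[dim - 3] += sgn * step_r
                pose, val = eval_at(c, rv)
                if val < cur_val - 1e-12:
                    com, rotvec, cur_pose, cur_val = c, rv, pose, val
                    improved = True
        if not improved:
            step_t *= 0.5
            step_r *= 0.5
            if step_t < 1e-4:
                break
    clash = cur_val > CLASH_LAMBDA
    if clash:
        warnings.warn("all candidate poses clash; returning least-bad pose",
                      RuntimeWarning, stacklevel=2)
    return cur_pose, float(cur_val), clash


def biased_segment(system: System, state: ThermoState, target_pose: Pose,
                   cfg: PathSearchConfig) -> ThermoState:
    """Run m Langevin steps pulling the ligand toward ``target_pose``.

    A constant-magnitude force along (target COM - current COM), re-evaluated
    every force call and distributed over ligand atoms in proportion to
    mass (a pure COM force), plus a weak torque aligning the ligand with
    the target orientation.  A zero separation gives a zero bias direction.
    """
    li = system.ligand_indices
    masses = system.masses
    mlig = masses[li]
    start_coords = state.positions
    body0 = start_coords[li] - np.average(start_coords[li], axis=0, weights=mlig)
    target_body = target_pose.apply(body0) - target_pose.com  # oriented body frame

    def bias(coords):
        f = np.zeros_like(coords)
        com = np.average(coords[li], axis=0, weights=mlig)
        d = target_pose.com - com
        norm = np.linalg.norm(d)
        if norm > 1e-10 and cfg.bias_force_magnitude > 0:
            f[li] += (cfg.bias_force_magnitude * d / norm)[None, :] * (mlig / mlig.sum())[:, None]
        if cfg.torque_constant > 0:
            rel = coords[li] - com
            rot, _, _ = _orientation_error(rel, target_body)
            rv = Rotation.from_matrix(rot).as_rotvec()
            if np.linalg.norm(rv) > 1e-10:
                f[li] += cfg.torque_constant * np.cross(rv, rel)
        return f

    return langevin_step(system, state, cfg.segment_steps, bias_force=bias)


def _orientation_error(rel: np.ndarray, target_rel: np.ndarray):
    """Proper rotation carrying the current body frame onto the target."""
    h = rel.T @ target_rel
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, None, None


def build_path(system: System, state0: ThermoState, lp: LambdaParams,
               cfg: PathSearchConfig, n_restarts: int = 2) -> Path:
    """Egress-path search with restarts.

    Runs :func:`_build_path_once` and, if the node budget is exhausted
    before egress, restarts from the bound state with a fresh proposal
    stream (up to ``n_restarts`` extra tries) -- the usual remedy for a
    population search trapped in a surface dimple.  Returns the first
    complete path, or the last (incomplete) attempt.
    """
    attempt = None
    for trial in range(n_restarts + 1):
        lp_t = lp if trial == 0 else replace(
            lp, rng_seed=int(np.random.SeedSequence([lp.rng_seed & 0x7FFFFFFF,
                                                     trial]).generate_state(1)[0] & 0x7FFFFFFF))
        with warnings.catch_warnings():
            if trial < n_restarts:
                warnings.simplefilter("ignore", RuntimeWarning)
            attempt = _build_path_once(system, state0, lp_t, cfg)
        if attempt.complete:
            return attempt
    return attempt


def _build_path_once(system: System, state0: ThermoState, lp: LambdaParams,
                     cfg: PathSearchConfig) -> Path:
    """Assemble the egress path S(1..N) by iterating propose -> minimize ->
    biased segment until the ligand COM leaves the cage or the node budget
    runs out (in which case the path is returned flagged incomplete).

    Successive target poses must increase the ligand-COM distance from the
    cage centre (by at least 0.1 * rho): the functional alone has a local
    minimum inside the cavity, and the monotonic egress constraint is what
    turns its minimization into a directed path search -- Lambda selects
    *where* to cross the boundary, the constraint enforces *that* it is
    crossed.
    """
    center = np.asarray(system.metadata.get("cage_center", (0.0, 0.0, 0.0)), float)
    li = system.ligand_indices
    state = state0.copy()
    nodes = [Conformation(state.positions.copy(), time=0.0, label="bound")]
    seeds = np.random.SeedSequence(lp.rng_seed).generate_state(cfg.max_nodes)
    complete = False
    for k in range(1, cfg.max_nodes):
        coords = state.positions
        com = _ligand_com(system, coords)
        prev = Pose(com)
        cur_r = float(np.linalg.norm(com - center))
        margin = 0.1 * lp.sphere_radius

        def outward(pose, _r=cur_r):
            return np.linalg.norm(pose.com - center) >= _r + margin

        lp_k = replace(lp, rng_seed=int(seeds[k] & 0x7FFFFFFF))
        cands = propose_candidates(prev, lp_k)
        lam_here = lambda_energy(system, Conformation(coords), lp_k)
        best_pose, best_val, _ = memetic_minimize(
            system, Conformation(coords), cands, lp_k, constraint=outward)
        if not np.isfinite(best_val) or best_val > lam_here + PRESSED_DELTA:
            # outward progress would press the ligand into the wall: allow a
            # tangential slide (non-decreasing radius) so the search can
            # follow the inner surface toward the tunnel mouth
            def tangential(pose, _r=cur_r):
                return np.linalg.norm(pose.com - center) >= _r

            slide_pose, slide_val, _ = memetic_minimize(
                system, Conformation(coords), cands, lp_k, constraint=tangential)
            if slide_val < best_val:
                best_pose, best_val = slide_pose, slide_val
        if not np.isfinite(best_val):
            # no feasible candidate this draw: densify the proposal cloud
            lp_dense = replace(lp_k, candidate_count=4 * lp_k.candidate_count)
            cands = propose_candidates(prev, lp_dense)
            best_pose, best_val, _ = memetic_minimize(
                system, Conformation(coords), cands, lp_dense, constraint=outward)
        state = biased_segment(system, state, best_pose, cfg)
        nodes.append(Conformation(state.positions.copy(),
                                  time=state.step_count * state.dt,
                                  label=f"node{k + 1}"))
        if np.linalg.norm(_ligand_com(system, state.positions) - center) >= cfg.termination_distance:
            complete = True
            break
    if not complete:
        warnings.warn("node budget exhausted before egress; path incomplete",
                      RuntimeWarning, stacklevel=2)
    env = system.environment_indices
    path = Path(nodes, alignment_set=env, displacement_set=li, complete=complete)
    path.refresh_metrics()
    return path


def reparameterize_path(path: Path, target_n: int,
                        simplify: bool = True) -> Path:
    """Resample to ``target_n`` nodes equidistant in displacement-set
    arc length; endpoints are preserved exactly.

    Raw search paths are noisy polylines that linger and loop while the
    ligand hunts along the inner surface, so with ``simplify=True`` the
    polyline is first shortcut-pruned (from each node, jump to the last
    later node within twice the median consecutive spacing) and lightly
    smoothed with a 3-node moving average before the equal-arc resampling
    (linear interpolation between surviving nodes after superposition onto
    the first node).
    """
    if target_n < 2:
        raise ParameterError("target_n must be >= 2")
    nodes = path.nodes
    align = path.alignment_set
    disp = path.displacement_set
    # superpose every node onto node 1 so arc length is measured consistently
    aligned = [np.asarray(nodes[0].coordinates, float)]
    for nd in nodes[1:]:
        _, _, moved = path_cv.kabsch_align(nd, nodes[0], align)
        aligned.append(moved)
    aligned = np.array(aligned)

    if simplify and len(aligned) > 3:
        dvecs = aligned[:, disp].reshape(len(aligned), -1)
        step = np.median(np.linalg.norm(np.diff(dvecs, axis=0), axis=1))
        keep = [0]
        i = 0
        while i < len(aligned) - 1:
            close = np.linalg.norm(dvecs[i + 1:] - dvecs[i], axis=1) <= 2.0 * step
            j = (i + 1 + np.max(np.nonzero(close)[0])) if np.any(close) else i + 1
            keep.append(j)
            i = j
        aligned = aligned[keep]
        if len(aligned) > 3:
            interior = 0.5 * aligned[1:-1] + 0.25 * (aligned[:-2] + aligned[2:])
            aligned = np.concatenate([aligned[:1], interior, aligned[-1:]])

    seg = np.linalg.norm(
        (aligned[1:, disp] - aligned[:-1, disp]).reshape(len(aligned) - 1, -1),
        axis=1)
    total = float(seg.sum())
    if total <= 1e-9:
        raise ParameterError("degenerate path: zero total length")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, target_n)
    new_nodes = [nodes[0].copy()]
    for t in targets[1:-1]:
        i = int(np.searchsorted(cum, t, side="right") - 1)
        i = min(i, len(seg) - 1)
        frac = (t - cum[i]) / seg[i] if seg[i] > 0 else 0.0
        coords = (1.0 - frac) * aligned[i] + frac * aligned[i + 1]
        new_nodes.append(Conformation(coords, label="resampled"))
    new_nodes.append(nodes[-1].copy())
    out = Path(new_nodes, align, disp, complete=path.complete)
    out.refresh_metrics()
    return out
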