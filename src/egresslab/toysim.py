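"""Toy particle systems and Langevin dynamics.

This module provides the desk-scale stand-ins for a protein--ligand complex:
analytic benchmark potentials (a 1D/2D double well) and a "cage" fixture --
a shell of harmonically tethered particles enclosing a rigid multi-atom
ligand, with one or more angular gaps playing the role of egress tunnels.

The dynamics is BAOAB-discretized Langevin dynamics in the NVT ensemble.
The ligand is propagated as a rigid body (net force on the centre of mass,
net torque about it); cage particles are independent point particles held
near their lattice sites by harmonic position restraints.  One-sided
harmonic walls on the ligand-COM distance from the cage centre mirror the
distance restraints used to keep a ligand inside a protein matrix during
biased runs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .constants import COULOMB_CONST, ENERGY_CONV, KB, R_MIN_CLAMP
from .exceptions import ConfigurationError, IntegrationError, ParameterError

ROLES = ("ligand", "protein", "anchor")

__all__ = [
    "AtomSpec",
    "Restraint",
    "Conformation",
    "System",
    "ThermoState",
    "make_double_well",
    "make_cage_ligand",
    "make_state_families",
    "potential_energy",
    "forces",
    "langevin_step",
    "sample_trajectory",
    "initial_state",
]


@dataclass
class AtomSpec:
    """Static per-atom parameters.

    ``partial_volume`` (A^3) and ``solvation_coefficient`` (kcal/mol/A^3)
    parameterize the desolvation-like Gaussian term of the path-search
    functional; they default to 1.0 and 0.0 so the term is opt-in.
    """

    id: int
    role: str
    mass: float = 12.0
    charge: float = 0.0
    lj_epsilon: float = 0.1
    lj_sigma: float = 3.0
    partial_volume: float = 1.0
    solvation_coefficient: float = 0.0

    def __post_init__(self):
        if self.role not in ROLES:
            raise ParameterError(f"unknown atom role {self.role!r}")
        if self.mass <= 0:
            raise ParameterError("atom mass must be positive")
        if self.lj_sigma <= 0:
            raise ParameterError("lj_sigma must be positive")


@dataclass
class Restraint:
    """A restraint term.

    kinds:
      - ``harmonicPosition``: each target atom tethered to its row of
        ``reference`` (an (n,3) array of site positions) with 1/2 k d^2.
      - ``distanceUpperWall``: one-sided harmonic on the distance between
        the COM of the target atoms and ``anchor`` (a fixed point); zero
        below ``reference``, 1/2 k (d - reference)^2 above.
      - ``cvUpperWall``: one-sided wall on a named collective variable
        (``targets`` is the CV name); applied by the biased-dynamics
        drivers, not by :func:`potential_energy`.
    """

    kind: str
    targets: object
    reference: object
    spring_constant: float
    anchor: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("harmonicPosition", "distanceUpperWall", "cvUpperWall"):
            raise ParameterError(f"unknown restraint kind {self.kind!r}")
        if self.spring_constant < 0:
            raise ParameterError("spring_constant must be >= 0")
        if self.kind == "harmonicPosition":
            self.targets = np.asarray(self.targets, dtype=int)
            self.reference = np.asarray(self.reference, dtype=float)
            if self.reference.shape != (len(self.targets), 3):
                raise ParameterError("harmonicPosition reference must be (n,3)")
        elif self.kind == "distanceUpperWall":
            self.targets = np.asarray(self.targets, dtype=int)
            self.anchor = np.zeros(3) if self.anchor is None else np.asarray(self.anchor, float)


@dataclass
class Conformation:
    """One snapshot: coordinates in A (an (n,3) array, or a length-d vector
    for analytic systems), a time stamp in ps and a free-text label."""

    coordinates: np.ndarray
    time: float = 0.0
    label: str = ""

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ParameterError("conformation coordinates must be finite")

    def copy(self) -> "Conformation":
        return Conformation(self.coordinates.copy(), self.time, self.label)


@dataclass
class System:
    """A simulatable system: atoms, rigid groupings, restraints and the
    potential kind (``pairwise3D`` | ``analytic1D`` | ``analytic2D``)."""

    atoms: list
    rigid_groups: list = field(default_factory=list)
    restraints: list = field(default_factory=list)
    potential_kind: str = "pairwise3D"
    analytic_params: dict = field(default_factory=dict)
    dielectric: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.potential_kind not in ("pairwise3D", "analytic1D", "analytic2D"):
            raise ParameterError(f"unknown potential kind {self.potential_kind!r}")
        ids = [a.id for a in self.atoms]
        if ids != list(range(len(self.atoms))):
            raise ConfigurationError("atom ids must be unique and contiguous from 0")
        if self.potential_kind == "pairwise3D" and not self.ligand_indices.size:
            raise ConfigurationError("pairwise3D system needs at least one ligand atom")
        n = len(self.atoms)
        for r in self.restraints:
            if r.kind != "cvUpperWall":
                if np.any(np.asarray(r.targets) >= n) or np.any(np.asarray(r.targets) < 0):
                    raise ConfigurationError("restraint references a non-existent atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def ligand_indices(self) -> np.ndarray:
        return np.array([a.id for a in self.atoms if a.role == "ligand"], dtype=int)

    @property
    def environment_indices(self) -> np.ndarray:
        """Cage/protein plus anchor atoms -- everything the ligand interacts with."""
        return np.array([a.id for a in self.atoms if a.role != "ligand"], dtype=int)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)


@dataclass
class ThermoState:
    """Dynamic state of a Langevin run.

    The noise stream for each :func:`langevin_step` call is derived from
    ``(rng_seed, step_count)``, so identical states give identical
    trajectories and successive calls never reuse noise.
    """

    positions: np.ndarray
    velocities: np.ndarray
    temperature: float = 300.0
    friction: float = 5.0
    dt: float = 0.002
    rng_seed: int = 0
    step_count: int = 0
    ang_velocities: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.temperature <= 0:
            raise ParameterError("target temperature must be positive")
        if self.dt <= 0:
            raise ParameterError("step size must be positive")

    def copy(self) -> "ThermoState":
        return ThermoState(
            self.positions.copy(), self.velocities.copy(), self.temperature,
            self.friction, self.dt, self.rng_seed, self.step_count,
            {k: v.copy() for k, v in self.ang_velocities.items()},
        )


# ---------------------------------------------------------------------------
# fixture constructors
# ---------------------------------------------------------------------------

def make_double_well(barrier: float, spacing: float, mass: float = 40.0,
                     dims: int = 1, k_perp: float = 10.0) -> System:
    """Analytic double-well benchmark, U(x) = barrier * ((x/spacing)^2 - 1)^2.

    Minima at x = +-spacing (U = 0), barrier height exactly ``barrier`` at
    x = 0.  With ``dims=2`` a harmonic transverse dof (k_perp, kcal/mol/A^2)
    is added.
    """
    if barrier <= 0 or spacing <= 0:
        raise ParameterError("barrier and spacing must be positive")
    if dims not in (1, 2):
        raise ParameterError("dims must be 1 or 2")
    kind = "analytic1D" if dims == 1 else "analytic2D"
    return System(
        atoms=[AtomSpec(0, "ligand", mass=mass)],
        potential_kind=kind,
        analytic_params={"barrier": float(barrier), "spacing": float(spacing),
                         "k_perp": float(k_perp)},
        metadata={"dims": dims},
    )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


_TUNNEL_AXES = {
    1: [(0.0, 0.0, 1.0)],
    2: [(0.0, 0.0, 1.0), (0.0, 0.0, -1.0)],
    3: [(1.0, 0.0, 0.0), (-0.5, math.sqrt(3) / 2, 0.0), (-0.5, -math.sqrt(3) / 2, 0.0)],
    4: [(1.0, 1.0, 1.0), (1.0, -1.0, -1.0), (-1.0, 1.0, -1.0), (-1.0, -1.0, 1.0)],
    5: [(0.0, 0.0, 1.0), (0.0, 0.0, -1.0), (1.0, 0.0, 0.0),
        (-0.5, math.sqrt(3) / 2, 0.0), (-0.5, -math.sqrt(3) / 2, 0.0)],
    6: [(1.0, 0.0, 0.0), (-1.0, 0.0, 0.0), (0.0, 1.0, 0.0),
        (0.0, -1.0, 0.0), (0.0, 0.0, 1.0), (0.0, 0.0, -1.0)],
}

_LIGAND_ARMS = np.array([
    [0.0, 0.0, 0.0],
    [1.2, 1.2, 1.2],
    [1.2, -1.2, -1.2],
    [-1.2, 1.2, -1.2],
    [-1.2, -1.2, 1.2],
]) / math.sqrt(3)


def make_cage_ligand(n_cage: int = 110, cage_radius: float = 10.0,
                     n_tunnels: int = 1, seed: int = 0,
                     tunnel_half_angle: float = math.radians(30.0),
                     restraint_k: float = 10.0,
                     wall_factor: float = 1.5) -> System:
    """Spherical cage with angular tunnel gaps enclosing a rigid ligand.

    ``n_cage`` lattice points are spread quasi-uniformly over a sphere of
    radius ``cage_radius``; points falling inside a cone of half-angle
    ``tunnel_half_angle`` around any tunnel axis are removed, leaving
    ``n_tunnels`` mouths wider than the ligand diameter.  A single "anchor"
    atom sits at the centre (the active-site metal analog); the rigid
    5-atom ligand starts off-centre at 0.3 * cage_radius.  Cage atoms are
    harmonically tethered to their sites and the ligand COM is held below
    ``wall_factor * cage_radius`` by a one-sided distance wall, mirroring
    the COM--metal distance restraint of biased unbinding runs.

    Deterministic given ``seed``; tunnel axes are stored in
    ``system.metadata['tunnel_axes']``.
    """
    if n_cage < 12:
        raise ParameterError("n_cage must be >= 12")
    if not 1 <= n_tunnels <= 6:
        raise ParameterError("n_tunnels must be in 1..6")
    lj_sigma = 3.0
    if cage_radius <= 2 * lj_sigma:
        raise ParameterError("cage_radius must exceed twice the LJ sigma")

    axes = np.array(_TUNNEL_AXES[n_tunnels], dtype=float)
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    # tunnels must be disjoint cones
    for i in range(n_tunnels):
        for j in range(i + 1, n_tunnels):
            sep = math.acos(np.clip(axes[i] @ axes[j], -1, 1))
            if sep <= 2 * tunnel_half_angle:
                raise ParameterError("tunnel cones overlap; reduce tunnel_half_angle")

    rng = np.random.default_rng(seed)
    pts = _fibonacci_sphere(n_cage)
    # seed-controlled global rotation of the lattice (tunnel axes stay fixed)
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
    pts = pts @ rot.T
    # small tangential jitter so the lattice is not perfectly regular
    jitter = rng.normal(scale=0.02 * cage_radius, size=pts.shape)
    jitter -= (np.sum(jitter * pts, axis=1, keepdims=True)) * pts
    cos_cut = math.cos(tunnel_half_angle)
    keep = np.max(pts @ axes.T, axis=1) < cos_cut
    cage_coords = cage_radius * pts[keep] + jitter[keep]
    if cage_coords.shape[0] < 8:
        raise ParameterError("tunnel gaps remove nearly the whole cage")

    # ligand start: off-centre, at least 45 degrees away from every tunnel axis
    for _ in range(256):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        if np.max(u @ axes.T) < math.cos(math.radians(45.0)):
            break
    else:
        u = -axes[0]
    lig_coords = 0.3 * cage_radius * u + _LIGAND_ARMS

    atoms, coords = [], []
    lig_idx = []
    for row in lig_coords:
        atoms.append(AtomSpec(len(atoms), "ligand", mass=12.0, lj_epsilon=0.25,
                              lj_sigma=2.8, partial_volume=1.0,
                              solvation_coefficient=1.0))
        lig_idx.append(atoms[-1].id)
        coords.append(row)
    atoms.append(AtomSpec(len(atoms), "anchor", mass=55.8, lj_epsilon=0.05,
                          lj_sigma=2.5, partial_volume=1.0,
                          solvation_coefficient=1.0))
    anchor_idx = atoms[-1].id
    coords.append(np.zeros(3))
    cage_idx = []
    for row in cage_coords:
        atoms.append(AtomSpec(len(atoms), "protein", mass=14.0, lj_epsilon=0.4,
                              lj_sigma=3.0, partial_volume=1.0,
                              solvation_coefficient=1.0))
        cage_idx.append(atoms[-1].id)
        coords.append(row)
    coords = np.array(coords)

    restraints = [
        Restraint("harmonicPosition", np.array([anchor_idx] + cage_idx),
                  coords[[anchor_idx] + cage_idx], restraint_k),
        Restraint("distanceUpperWall", np.array(lig_idx),
                  wall_factor * cage_radius, 10.0, anchor=np.zeros(3)),
    ]
    sys_ = System(
        atoms=atoms,
        rigid_groups=[lig_idx],
        restraints=restraints,
        potential_kind="pairwise3D",
        metadata={
            "cage_radius": cage_radius,
            "cage_center": [0.0, 0.0, 0.0],
            "tunnel_axes": axes.tolist(),
            "tunnel_half_angle": tunnel_half_angle,
            "seed": seed,
        },
    )
    sys_.metadata["initial_coordinates"] = coords.tolist()
    return sys_


def make_state_families(system: System, n_closed: int, n_open: int,
                        displacement: float = 3.0, noise: float = 0.3,
                        seed: int = 0):
    """Two planted conformer families of the cage fixture.

    "Closed" frames are the reference cage with isotropic Gaussian noise on
    every atom; "open" frames additionally push the cage atoms bordering
    the first tunnel mouth radially outward by ``displacement`` A -- a toy
    analog of a gate opening.  Returns (conformations, true_labels) with
    label 0 = closed, 1 = open, in shuffled order.
    """
    rng = np.random.default_rng(seed)
    ref = np.array(system.metadata["initial_coordinates"])
    axes = np.array(system.metadata["tunnel_axes"])
    half = system.metadata["tunnel_half_angle"]
    cage = system.environment_indices
    r = ref[cage]
    norms = np.linalg.norm(r, axis=1, keepdims=True)
    rn = np.divide(r, norms, out=np.zeros_like(r), where=norms > 1e-9)
    gate = cage[(rn @ axes[0]) > math.cos(half * 1.8)]
    confs, labels = [], []
    for fam, n in ((0, n_closed), (1, n_open)):
        for _ in range(n):
            c = ref + rng.normal(scale=noise, size=ref.shape)
            if fam == 1:
                d = ref[gate] / np.linalg.norm(ref[gate], axis=1, keepdims=True)
                c[gate] += displacement * d
            confs.append(Conformation(c, label="open" if fam else "closed"))
            labels.append(fam)
    order = rng.permutation(len(confs))
    return [confs[i] for i in order], np.array(labels)[order]


# ---------------------------------------------------------------------------
# energies and forces
# ---------------------------------------------------------------------------

def _analytic_energy_grad(system: System, x: np.ndarray):
    p = system.analytic_params
    b, a = p["barrier"], p["spacing"]
    x = np.atleast_1d(np.asarray(x, float))
    u = b * ((x[0] / a) ** 2 - 1.0) ** 2
    g = np.zeros_like(x)
    g[0] = 4.0 * b * x[0] * ((x[0] / a) ** 2 - 1.0) / a ** 2
    if x.size > 1:
        k = p.get("k_perp", 10.0)
        u += 0.5 * k * np.sum(x[1:] ** 2)
        g[1:] = k * x[1:]
    return u, g


def _nonbonded(system: System, coords: np.ndarray):
    """LJ 12-6 + Coulomb over ligand x environment pairs.

    Returns (e_vdw, e_coul, forces).  Distances are clamped at
    ``R_MIN_CLAMP`` so overlapping atoms give a large finite energy.
    """
    li = system.ligand_indices
    ei = system.environment_indices
    f = np.zeros_like(coords)
    if li.size == 0 or ei.size == 0:
        return 0.0, 0.0, f
    eps = np.array([a.lj_epsilon for a in system.atoms])
    sig = np.array([a.lj_sigma for a in system.atoms])
    q = np.array([a.charge for a in system.atoms])
    d = coords[li][:, None, :] - coords[ei][None, :, :]
    r = np.linalg.norm(d, axis=2)
    clamped = r < R_MIN_CLAMP
    if np.any(clamped):
        warnings.warn("atom overlap: pair distance clamped at "
                      f"{R_MIN_CLAMP} A", RuntimeWarning, stacklevel=3)
    rc = np.maximum(r, R_MIN_CLAMP)
    sij = 0.5 * (sig[li][:, None] + sig[ei][None, :])
    eij = np.sqrt(eps[li][:, None] * eps[ei][None, :])
    sr6 = (sij / rc) ** 6
    e_vdw = float(np.sum(4.0 * eij * (sr6 ** 2 - sr6)))
    qq = q[li][:, None] * q[ei][None, :]
    e_coul = float(np.sum(COULOMB_CONST * qq / (system.dielectric * rc)))
    # dE/dr; zero force inside the clamp (energy is flat there)
    dEdr = np.where(clamped, 0.0,
                    4.0 * eij * (-12.0 * sr6 ** 2 + 6.0 * sr6) / rc
                    - COULOMB_CONST * qq / (system.dielectric * rc ** 2))
    fpair = -dEdr[:, :, None] * d / rc[:, :, None]
    np.add.at(f, li, np.sum(fpair, axis=1))
    np.add.at(f, ei, -np.sum(fpair, axis=0))
    return e_vdw, e_coul, f


def _restraint_terms(system: System, coords: np.ndarray):
    e = 0.0
    f = np.zeros_like(coords)
    masses = system.masses
    for r in system.restraints:
        if r.kind == "harmonicPosition":
            d = coords[r.targets] - r.reference
            e += 0.5 * r.spring_constant * float(np.sum(d * d))
            f[r.targets] -= r.spring_constant * d
        elif r.kind == "distanceUpperWall":
            m = masses[r.targets]
            com = np.average(coords[r.targets], axis=0, weights=m)
            v = com - r.anchor
            dist = float(np.linalg.norm(v))
            if dist > float(r.reference):
                e += 0.5 * r.spring_constant * (dist - float(r.reference)) ** 2
                fcom = -r.spring_constant * (dist - float(r.reference)) * v / dist
                f[r.targets] += fcom[None, :] * (m / m.sum())[:, None]
        # cvUpperWall handled by the biased-dynamics drivers
    return e, f


def potential_energy(system: System, conf: Conformation) -> dict:
    """Energy decomposition {vdw, coulomb, restraint, analytic, total}, kcal/mol.

    Pure function of its inputs; ``total`` is the sum of the parts.
    """
    coords = conf.coordinates
    if system.potential_kind in ("analytic1D", "analytic2D"):
        u, _ = _analytic_energy_grad(system, coords)
        parts = {"vdw": 0.0, "coulomb": 0.0, "restraint": 0.0, "analytic": float(u)}
    else:
        if coords.shape != (system.n_atoms, 3):
            raise ConfigurationError("conformation does not match system atom count")
        e_vdw, e_coul, _ = _nonbonded(system, coords)
        e_res, _ = _restraint_terms(system, coords)
        parts = {"vdw": e_vdw, "coulomb": e_coul, "restraint": e_res, "analytic": 0.0}
    parts["total"] = sum(parts.values())
    return parts


def forces(system: System, coords: np.ndarray) -> np.ndarray:
    """Total force (kcal/mol/A) on every atom (or dof for analytic systems)."""
    if system.potential_kind in ("analytic1D", "analytic2D"):
        _, g = _analytic_energy_grad(system, coords)
        return -g
    _, _, f = _nonbonded(system, coords)
    _, fr = _restraint_terms(system, coords)
    return f + fr


# ---------------------------------------------------------------------------
# Langevin dynamics (BAOAB)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _analytic_baoab_core(x, v, nsteps, dt, friction, kT_int, mass,
                         barrier, spacing, k_perp, seed, record_stride,
                         rec, rec_v):
    np.random.seed(seed)
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1)) * math.sqrt(kT_int / mass)
    d = x.shape[0]
    conv = ENERGY_CONV / mass
    g = np.empty(d)
    nrec = 0
    for step in range(nsteps):
        g[0] = 4.0 * barrier * x[0] * ((x[0] / spacing) ** 2 - 1.0) / spacing ** 2
        for j in range(1, d):
            g[j] = k_perp * x[j]
        for j in range(d):
            v[j] += 0.5 * dt * (-g[j]) * conv
            x[j] += 0.5 * dt * v[j]
            v[j] = c1 * v[j] + c2 * np.random.normal()
            x[j] += 0.5 * dt * v[j]
        g[0] = 4.0 * barrier * x[0] * ((x[0] / spacing) ** 2 - 1.0) / spacing ** 2
        for j in range(1, d):
            g[j] = k_perp * x[j]
        for j in range(d):
            v[j] += 0.5 * dt * (-g[j]) * conv
        if record_stride > 0 and (step + 1) % record_stride == 0:
            rec[nrec] = x[0]
            rec_v[nrec] = v[0]
            nrec += 1
    return nrec


def _derive_seed(rng_seed: int, step_count: int) -> int:
    ss = np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF, int(step_count)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def initial_state(system: System, temperature: float = 300.0,
                  friction: float = 5.0, dt: float = 0.002,
                  seed: int = 0) -> ThermoState:
    """State at the fixture's reference coordinates with Maxwellian velocities."""
    rng = np.random.default_rng(seed)
    if system.potential_kind == "pairwise3D":
        x = np.array(system.metadata["initial_coordinates"], dtype=float)
        sig = np.sqrt(KB * temperature * ENERGY_CONV / system.masses)
        v = rng.normal(size=x.shape) * sig[:, None]
    else:
        d = 1 if system.potential_kind == "analytic1D" else 2
        x = np.full(d, -system.analytic_params["spacing"])
        x[1:] = 0.0
        sig = math.sqrt(KB * temperature * ENERGY_CONV / system.atoms[0].mass)
        v = rng.normal(size=d) * sig
    return ThermoState(x, v, temperature, friction, dt, rng_seed=seed)


def _rigid_body_step(system: System, coords, vels, ang_vels, dt, c1, kT_int,
                     masses, force_fn):
    """One BAOAB step; rigid groups move as translating + rotating units."""
    from scipy.spatial.transform import Rotation

    rigid = system.rigid_groups
    in_rigid = np.zeros(len(masses), dtype=bool)
    for grp in rigid:
        in_rigid[grp] = True
    free = ~in_rigid
    c2v = np.sqrt(max(0.0, 1.0 - c1 * c1)) * np.sqrt(kT_int / masses)
    rng_normal = force_fn.rng.normal  # noise shared per call

    def body_update(grp, f, half_kick_only=False):
        idx = np.asarray(grp)
        m = masses[idx]
        M = m.sum()
        com = np.average(coords[idx], axis=0, weights=m)
        vcom = np.average(vels[idx], axis=0, weights=m)
        fnet = f[idx].sum(axis=0)
        rel = coords[idx] - com
        torque = np.sum(np.cross(rel, f[idx]), axis=0)
        inertia = np.sum(m * np.sum(rel * rel, axis=1))  # isotropic approx, amu A^2
        inertia = max(inertia, 1e-6)
        w = ang_vels.setdefault(id(grp) if False else tuple(grp), np.zeros(3))
        vcom = vcom + 0.5 * dt * fnet * ENERGY_CONV / M
        w = w + 0.5 * dt * torque * ENERGY_CONV / inertia
        if not half_kick_only:
            com_new = com + 0.5 * dt * vcom
            rot = Rotation.from_rotvec(w * (0.5 * dt)).as_matrix()
            rel = rel @ rot.T
            # O step
            vcom = c1 * vcom + math.sqrt(max(0.0, 1 - c1 * c1)) * math.sqrt(kT_int / M) * rng_normal(size=3)
            w = c1 * w + math.sqrt(max(0.0, 1 - c1 * c1)) * math.sqrt(kT_int / inertia) * rng_normal(size=3)
            com_new = com_new + 0.5 * dt * vcom
            rot = Rotation.from_rotvec(w * (0.5 * dt)).as_matrix()
            rel = rel @ rot.T
            coords[idx] = com_new + rel
        vels[idx] = vcom + np.cross(w, rel)
        ang_vels[tuple(grp)] = w

    f = force_fn(coords)
    if not np.all(np.isfinite(f)):
        bad = int(np.argwhere(~np.isfinite(f))[0][0])
        raise IntegrationError(f"non-finite force on atom {bad}")
    # B + A + O + A for free atoms
    vels[free] += 0.5 * dt * f[free] * ENERGY_CONV / masses[free, None]
    for grp in rigid:
        body_update(grp, f)
    coords[free] += 0.5 * dt * vels[free]
    vels[free] = c1 * vels[free] + c2v[free, None] * force_fn.rng.normal(size=(int(free.sum()), 3))
    coords[free] += 0.5 * dt * vels[free]
    # final B kick with fresh forces
    f = force_fn(coords)
    if not np.all(np.isfinite(f)):
        bad = int(np.argwhere(~np.isfinite(f))[0][0])
        raise IntegrationError(f"non-finite force on atom {bad}")
    vels[free] += 0.5 * dt * f[free] * ENERGY_CONV / masses[free, None]
    for grp in rigid:
        body_update(grp, f, half_kick_only=True)


def langevin_step(system: System, state: ThermoState, n_steps: int,
                  bias_force=None) -> ThermoState:
    """Advance ``n_steps`` of BAOAB Langevin dynamics; returns a new state.

    ``bias_force(coords) -> forces`` adds an external force field (used by
    the biased-pulling and metadynamics drivers).  Deterministic given the
    state's ``rng_seed`` and ``step_count``.
    """
    if n_steps < 1:
        raise ParameterError("n_steps must be >= 1")
    out = state.copy()
    seed32 = _derive_seed(state.rng_seed, state.step_count)
    if system.potential_kind in ("analytic1D", "analytic2D") and bias_force is None:
        rec = np.empty(0)
        nrec = _analytic_baoab_core(
            out.positions, out.velocities, n_steps, out.dt, out.friction,
            KB * out.temperature * ENERGY_CONV, system.atoms[0].mass,
            system.analytic_params["barrier"], system.analytic_params["spacing"],
            system.analytic_params.get("k_perp", 10.0), seed32, 0, rec, rec)
        out.step_count += n_steps
        return out
    if system.potential_kind in ("analytic1D", "analytic2D"):
        # python path with bias, analytic dof
        rng = np.random.default_rng(np.random.SeedSequence([state.rng_seed & 0x7FFFFFFF, state.step_count]))
        m = system.atoms[0].mass
        c1 = math.exp(-out.friction * out.dt)
        c2 = math.sqrt(max(0.0, 1 - c1 * c1)) * math.sqrt(KB * out.temperature * ENERGY_CONV / m)
        x, v = out.positions, out.velocities
        for _ in range(n_steps):
            f = forces(system, x) + bias_force(x)
            v += 0.5 * out.dt * f * ENERGY_CONV / m
            x += 0.5 * out.dt * v
            v = c1 * v + c2 * rng.normal(size=x.shape)
            x += 0.5 * out.dt * v
            f = forces(system, x) + bias_force(x)
            v += 0.5 * out.dt * f * ENERGY_CONV / m
        out.positions, out.velocities = x, v
        out.step_count += n_steps
        return out

    rng = np.random.default_rng(np.random.SeedSequence([state.rng_seed & 0x7FFFFFFF, state.step_count]))
    masses = system.masses
    c1 = math.exp(-out.friction * out.dt)
    kT_int = KB * out.temperature * ENERGY_CONV

    def force_fn(coords):
        f = forces(system, coords)
        if bias_force is not None:
            f = f + bias_force(coords)
        return f

    force_fn.rng = rng
    for _ in range(n_steps):
        _rigid_body_step(system, out.positions, out.velocities,
                         out.ang_velocities, out.dt, c1, kT_int, masses, force_fn)
    out.step_count += n_steps
    return out


def sample_trajectory(system: System, state: ThermoState, n_steps: int,
                      record_stride: int = 100) -> tuple:
    """Unbiased run recording the first coordinate every ``record_stride``
    steps (analytic systems only; used for sampling diagnostics).

    Returns (position_samples, velocity_samples, final_state).
    """
    if system.potential_kind == "pairwise3D":
        raise ConfigurationError("sample_trajectory supports analytic systems only")
    out = state.copy()
    seed32 = _derive_seed(state.rng_seed, state.step_count)
    rec = np.empty(n_steps // record_stride)
    rec_v = np.empty(n_steps // record_stride)
    nrec = _analytic_baoab_core(
        out.positions, out.velocities, n_steps, out.dt, out.friction,
        KB * out.temperature * ENERGY_CONV, system.atoms[0].mass,
        system.analytic_params["barrier"], system.analytic_params["spacing"],
        system.analytic_params.get("k_perp", 10.0), seed32, record_stride,
        rec, rec_v)
    out.step_count += n_steps
    return rec[:nrec], rec_v[:nrec], out
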