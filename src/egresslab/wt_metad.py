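"""Well-tempered metadynamics with adaptive Gaussians.

A history-dependent bias V(xi, t) is built as a sum of Gaussian kernels
deposited along the trajectory of the collective variable xi.  In the
well-tempered protocol each new kernel's height is damped by the bias
already present,

    h = h0 * exp(-V(xi)/(kB * deltaT)),

so the bias converges and the free energy follows from the
time-independent estimator

    F(xi, t) = -((T + deltaT)/deltaT) * V(xi, t),

normalized so min F = 0.  Observables are recovered from biased frames by
weighting each frame with exp(beta * (V(xi(t), t) - c(t))), where

    c(t) = (1/beta) * ln [ Int dxi e^{-beta F(xi)} / Int dxi e^{-beta (F(xi)+V(xi,t))} ].

Adaptive Gaussian widths follow the time-domain scheme: the width of a new
kernel is the standard deviation of the CV over a trailing window (default
0.25 ps), floored to avoid spike kernels.  Default deposition parameters
(h0 = 0.48 kcal/mol every 0.25 ps, i.e. a rate of 1.92 kcal/mol per ps,
T = 300 K, deltaT = 3300 K) match common practice for ligand-egress runs.

Convergence is diagnosed from the kernel-height trace: a run is considered
converged when the residual height (mean over the final 5% of kernels)
falls below 1% of h0, alongside block standard errors of the profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import logsumexp

from .constants import ENERGY_CONV, KB
from .exceptions import ParameterError
from .toysim import System

__all__ = [
    "GaussianKernel",
    "BiasState",
    "FreeEnergyProfile",
    "bias_potential",
    "bias_derivative",
    "deposit_gaussian",
    "adaptive_width",
    "z_wall_force",
    "free_energy_estimate",
    "reweight_constant",
    "reweighted_histogram",
    "convergence_report",
    "run_metad_double_well",
    "run_pcv_metad",
]


@dataclass
class GaussianKernel:
    center: float
    width: float
    height: float
    deposit_time: float

    def __post_init__(self):
        if self.width <= 0:
            raise ParameterError("kernel width must be positive")
        if self.height < 0:
            raise ParameterError("kernel height must be >= 0")


@dataclass
class BiasState:
    """The deposited bias: kernel list plus the tempering parameters."""

    temperature: float = 300.0
    delta_t: float = 3300.0
    initial_height: float = 0.48
    deposit_interval: float = 0.25
    adaptive_window: float = 0.25
    width_floor: float = 0.01
    kernels: list = field(default_factory=list)

    def __post_init__(self):
        if self.delta_t <= 0:
            raise ParameterError("deltaT must be positive")

    @property
    def bias_factor(self) -> float:
        return (self.temperature + self.delta_t) / self.temperature

    def kernel_arrays(self):
        if not self.kernels:
            z = np.empty(0)
            return z, z, z, z
        c = np.array([k.center for k in self.kernels])
        w = np.array([k.width for k in self.kernels])
        h = np.array([k.height for k in self.kernels])
        t = np.array([k.deposit_time for k in self.kernels])
        return c, w, h, t


@dataclass
class FreeEnergyProfile:
    grid: np.ndarray
    free_energy: np.ndarray
    standard_error: np.ndarray | None = None
    reweighted: bool = False

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float)
        self.free_energy = np.asarray(self.free_energy, float)
        if np.any(np.diff(self.grid) <= 0):
            raise ParameterError("grid must be strictly increasing")

    def barrier_height(self) -> float:
        """Max(F) between the two outermost minima (kcal/mol)."""
        f = self.free_energy
        imin1 = int(np.argmin(f[: len(f) // 2]))
        imin2 = len(f) // 2 + int(np.argmin(f[len(f) // 2:]))
        return float(np.max(f[imin1:imin2 + 1]) - 0.5 * (f[imin1] + f[imin2]))


def bias_potential(bias: BiasState, s) -> float | np.ndarray:
    """V(s) = sum of deposited Gaussians; 0 for an empty bias."""
    c, w, h, _ = bias.kernel_arrays()
    s_arr = np.atleast_1d(np.asarray(s, float))
    if c.size == 0:
        out = np.zeros_like(s_arr)
    else:
        out = np.sum(h * np.exp(-(s_arr[:, None] - c) ** 2 / (2.0 * w ** 2)), axis=1)
    return float(out[0]) if np.isscalar(s) or np.ndim(s) == 0 else out


def bias_derivative(bias: BiasState, s: float) -> float:
    """dV/ds at a scalar CV value."""
    c, w, h, _ = bias.kernel_arrays()
    if c.size == 0:
        return 0.0
    d = s - c
    return float(np.sum(h * np.exp(-d ** 2 / (2 * w ** 2)) * (-d / w ** 2)))


def deposit_gaussian(bias: BiasState, s_value: float, width_now: float,
                     time: float = 0.0) -> BiasState:
    """Append one well-tempered kernel; the damped height is computed from
    the bias *before* deposition."""
    if width_now <= 0:
        raise ParameterError("width_now must be positive")
    v_here = bias_potential(bias, s_value)
    h = bias.initial_height * math.exp(-v_here / (KB * bias.delta_t))
    bias.kernels.append(GaussianKernel(float(s_value), float(width_now), h, float(time)))
    return bias


def adaptive_width(times: np.ndarray, values: np.ndarray, tau: float,
                   floor: float = 0.01) -> float:
    """Time-domain adaptive width: std of the CV over the trailing window
    of length ``tau`` (ps), floored at ``floor``."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if times.size < 2 or times[-1] - times[0] < tau:
        raise ParameterError("CV history must span at least the window tau")
    mask = times >= times[-1] - tau
    if mask.sum() < 2:
        raise ParameterError("window tau is shorter than the sampling interval")
    return max(float(np.std(values[mask])), floor)


def z_wall_force(z_value: float, limit: float = 6.0,
                 kappa: float = 100.0):
    """One-sided harmonic wall keeping the path deviation z below ``limit``
    (A^2).  Returns (energy kcal/mol, dE/dz kcal/mol/A^2); both vanish
    continuously at the wall."""
    if kappa <= 0:
        raise ParameterError("kappa must be positive")
    if z_value <= limit:
        return 0.0, 0.0
    d = z_value - limit
    return 0.5 * kappa * d * d, kappa * d


def free_energy_estimate(bias: BiasState, grid: np.ndarray) -> FreeEnergyProfile:
    """Time-independent estimator F = -((T+deltaT)/deltaT) V, min-shifted to 0."""
    if not bias.kernels:
        raise ParameterError("bias is empty")
    v = bias_potential(bias, np.asarray(grid, float))
    f = -(bias.temperature + bias.delta_t) / bias.delta_t * v
    f -= f.min()
    return FreeEnergyProfile(np.asarray(grid, float), f)


def _bias_at_time(bias: BiasState, grid: np.ndarray, t: float) -> np.ndarray:
    c, w, h, tk = bias.kernel_arrays()
    sel = tk <= t
    if not np.any(sel):
        return np.zeros_like(grid)
    return np.sum(h[sel] * np.exp(-(grid[:, None] - c[sel]) ** 2 / (2 * w[sel] ** 2)), axis=1)


def reweight_constant(bias: BiasState, grid: np.ndarray, t: float,
                      profile: FreeEnergyProfile | None = None) -> float:
    """The time-dependent offset c(t) by trapezoid quadrature on the grid,
    log-sum-exp stabilized.  ``profile`` defaults to the final estimator."""
    grid = np.asarray(grid, float)
    if grid.size < 2:
        raise ParameterError("grid must have at least 2 points")
    if profile is None:
        profile = free_energy_estimate(bias, grid)
    beta = 1.0 / (KB * bias.temperature)
    f = np.interp(grid, profile.grid, profile.free_energy)
    v = _bias_at_time(bias, grid, t)
    wtrap = np.gradient(grid)
    num = logsumexp(-beta * f, b=wtrap)
    den = logsumexp(-beta * (f + v), b=wtrap)
    return float((num - den) / beta)


def frame_weights(times: np.ndarray, s_values: np.ndarray, bias: BiasState,
                  grid: np.ndarray) -> np.ndarray:
    """Normalized time-independent frame weights exp(beta(V(s_t,t) - c(t))).

    One chronological pass maintains the cumulative bias on ``grid``:
    each frame's V(s_t, t) includes exactly the kernels deposited before
    it (grid-interpolated), and c(t) is re-quadratured whenever a kernel
    is absorbed.
    """
    times = np.asarray(times, float)
    s_values = np.asarray(s_values, float)
    grid = np.asarray(grid, float)
    beta = 1.0 / (KB * bias.temperature)
    c, w, h, tk = bias.kernel_arrays()
    if c.size == 0:
        return np.full(times.size, 1.0 / times.size)
    profile = free_energy_estimate(bias, grid)
    f = profile.free_energy
    wtrap = np.gradient(grid)
    log_num = logsumexp(-beta * f, b=wtrap)
    order = np.argsort(times, kind="stable")
    vgrid = np.zeros_like(grid)
    logw = np.empty(times.size)
    k = 0
    ct = (log_num - logsumexp(-beta * f, b=wtrap)) / beta  # = 0 for V = 0
    for i in order:
        t = times[i]
        absorbed = False
        while k < c.size and tk[k] <= t:
            vgrid += h[k] * np.exp(-(grid - c[k]) ** 2 / (2 * w[k] ** 2))
            k += 1
            absorbed = True
        if absorbed:
            ct = (log_num - logsumexp(-beta * (f + vgrid), b=wtrap)) / beta
        v_here = float(np.interp(s_values[i], grid, vgrid))
        logw[i] = beta * (v_here - ct)
    logw -= logsumexp(logw)
    return np.exp(logw)


def reweighted_histogram(times, observable, s_values, bias: BiasState,
                         grid: np.ndarray, bins=50, value_range=None,
                         discard_fraction: float = 0.2):
    """Weighted distribution of an observable from a biased trajectory.

    The leading ``discard_fraction`` of the frames is dropped as the
    filling transient: before the bias first saturates a basin the system
    is far from the quasi-stationary regime the reweighting assumes, and
    those frames otherwise carry spuriously large weights.

    Returns (bin_centers, density, weights); weights are positive and sum
    to 1, and with an empty bias the histogram equals the raw one.
    """
    times = np.asarray(times, float)
    observable = np.asarray(observable, float)
    s_values = np.asarray(s_values, float)
    i0 = int(discard_fraction * times.size)
    times, observable, s_values = times[i0:], observable[i0:], s_values[i0:]
    wts = frame_weights(times, s_values, bias, np.asarray(grid, float))
    hist, edges = np.histogram(observable, bins=bins, range=value_range,
                               weights=wts, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, hist, wts


def convergence_report(bias: BiasState, blocks: int = 4,
                       grid: np.ndarray | None = None) -> dict:
    """Height trace, residual-height fraction and block standard errors.

    residual fraction = mean height of the final 5% of kernels / h0 (< 0.01
    marks a converged well-tempered run).  Block SEs are computed from
    free-energy estimates at ``blocks`` checkpoints over the second half of
    the deposition history, each mean-centred to remove the arbitrary
    offset.
    """
    if len(bias.kernels) < 2:
        raise ParameterError("need at least 2 deposited kernels")
    if blocks < 2:
        raise ParameterError("blocks must be >= 2")
    c, w, h, tk = bias.kernel_arrays()
    ntail = max(1, int(round(0.05 * h.size)))
    residual = float(np.mean(h[-ntail:]) / bias.initial_height)
    out = {
        "height_trace": (tk.copy(), h.copy()),
        "residual_height_fraction": residual,
    }
    if grid is not None:
        grid = np.asarray(grid, float)
        checkpoints = np.linspace(0.5, 1.0, blocks + 1)[1:] * tk[-1]
        ests = []
        scale = -(bias.temperature + bias.delta_t) / bias.delta_t
        for t in checkpoints:
            f = scale * _bias_at_time(bias, grid, t)
            ests.append(f - f.mean())
        ests = np.array(ests)
        out["block_se"] = ests.std(axis=0, ddof=1) / math.sqrt(blocks)
        out["mean_block_se"] = float(np.mean(out["block_se"]))
    return out


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

@njit(cache=False)
def _metad1d_core(x0, v0, nsteps, dt, friction, kT_int, mass, barrier, spacing,
                  deposit_stride, window_steps, h0, kdT, width_floor,
                  grid, vgrid, dvgrid, seed, record_stride,
                  kc, kw, kh, kt, rec_t, rec_x, rec_v):
    """BAOAB + on-the-fly well-tempered deposition on a bias grid.

    The bias and its derivative live on ``grid``; each deposit adds one
    Gaussian analytically to both.  Returns (n_kernels, n_records)."""
    np.random.seed(seed)
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1)) * math.sqrt(kT_int / mass)
    conv = ENERGY_CONV / mass
    x, v = x0, v0
    g0 = grid[0]
    dg = grid[1] - grid[0]
    ng = grid.shape[0]
    nker = 0
    nrec = 0
    hist = np.empty(window_steps)
    hn = 0

    for step in range(nsteps):
        # interpolated bias force
        u = (x - g0) / dg
        i = int(u)
        if i < 0:
            i = 0
        if i > ng - 2:
            i = ng - 2
        frac = u - i
        fbias = -((1.0 - frac) * dvgrid[i] + frac * dvgrid[i + 1])
        fphys = -4.0 * barrier * x * ((x / spacing) ** 2 - 1.0) / spacing ** 2
        v += 0.5 * dt * (fphys + fbias) * conv
        x += 0.5 * dt * v
        v = c1 * v + c2 * np.random.normal()
        x += 0.5 * dt * v
        u = (x - g0) / dg
        i = int(u)
        if i < 0:
            i = 0
        if i > ng - 2:
            i = ng - 2
        frac = u - i
        fbias = -((1.0 - frac) * dvgrid[i] + frac * dvgrid[i + 1])
        fphys = -4.0 * barrier * x * ((x / spacing) ** 2 - 1.0) / spacing ** 2
        v += 0.5 * dt * (fphys + fbias) * conv
        # trailing CV window (ring buffer)
        hist[step % window_steps] = x
        if hn < window_steps:
            hn += 1
        # deposit
        if (step + 1) % deposit_stride == 0 and hn >= window_steps:
            mu = 0.0
            for j in range(window_steps):
                mu += hist[j]
            mu /= window_steps
            var = 0.0
            for j in range(window_steps):
                var += (hist[j] - mu) ** 2
            width = math.sqrt(var / window_steps)
            if width < width_floor:
                width = width_floor
            vhere = (1.0 - frac) * vgrid[i] + frac * vgrid[i + 1]
            h = h0 * math.exp(-vhere / kdT)
            kc[nker] = x
            kw[nker] = width
            kh[nker] = h
            kt[nker] = (step + 1) * dt
            nker += 1
            inv2w2 = 1.0 / (2.0 * width * width)
            for j in range(ng):
                d = grid[j] - x
                e = h * math.exp(-d * d * inv2w2)
                vgrid[j] += e
                dvgrid[j] += e * (-d) * (2.0 * inv2w2)
        if record_stride > 0 and (step + 1) % record_stride == 0:
            rec_t[nrec] = (step + 1) * dt
            rec_x[nrec] = x
            rec_v[nrec] = v
            nrec += 1
    return nker, nrec, x, v


def run_metad_double_well(system: System, n_steps: int, seed: int = 0,
                          temperature: float = 300.0, delta_t: float = 3300.0,
                          initial_height: float = 0.48,
                          deposit_interval: float = 0.25,
                          adaptive_window: float = 0.25,
                          width_floor: float = 0.02,
                          friction: float = 5.0, dt: float = 0.002,
                          grid_range=(-2.5, 2.5), n_grid: int = 1001,
                          record_stride: int = 250) -> dict:
    """Well-tempered metadynamics on the analytic double well, biasing the
    x coordinate directly.

    Returns a dict with the populated ``BiasState``, the recorded colvar
    arrays (times, x) and the bias grid.  Deterministic given ``seed``.
    """
    if system.potential_kind != "analytic1D":
        raise ParameterError("run_metad_double_well needs an analytic1D system")
    p = system.analytic_params
    mass = system.atoms[0].mass
    grid = np.linspace(grid_range[0], grid_range[1], n_grid)
    vgrid = np.zeros(n_grid)
    dvgrid = np.zeros(n_grid)
    deposit_stride = max(1, int(round(deposit_interval / dt)))
    window_steps = max(2, int(round(adaptive_window / dt)))
    max_k = n_steps // deposit_stride + 1
    kc = np.empty(max_k)
    kw = np.empty(max_k)
    kh = np.empty(max_k)
    kt = np.empty(max_k)
    nrec_max = n_steps // record_stride + 1 if record_stride > 0 else 1
    rec_t = np.empty(nrec_max)
    rec_x = np.empty(nrec_max)
    rec_v = np.empty(nrec_max)
    seed32 = int(np.random.SeedSequence(seed & 0x7FFFFFFF).generate_state(1, dtype=np.uint32)[0])
    x0 = -p["spacing"]
    nker, nrec, xf, vf = _metad1d_core(
        x0, 0.0, n_steps, dt, friction, KB * temperature * ENERGY_CONV, mass,
        p["barrier"], p["spacing"], deposit_stride, window_steps,
        initial_height, KB * delta_t, width_floor, grid, vgrid, dvgrid,
        seed32, record_stride, kc, kw, kh, kt, rec_t, rec_x, rec_v)
    bias = BiasState(temperature, delta_t, initial_height, deposit_interval,
                     adaptive_window, width_floor)
    bias.kernels = [GaussianKernel(kc[i], kw[i], kh[i], kt[i]) for i in range(nker)]
    return {
        "bias": bias,
        "times": rec_t[:nrec].copy(),
        "cv": rec_x[:nrec].copy(),
        "grid": grid,
        "v_grid": vgrid,
        "final_x": xf,
        "final_v": vf,
    }


def run_pcv_metad(system: System, path, state, n_steps: int,
                  temperature: float = 300.0, delta_t: float = 3300.0,
                  initial_height: float = 0.48, deposit_interval: float = 0.25,
                  adaptive_window: float = 0.25, width_floor: float = 0.05,
                  z_limit: float = 6.0, z_kappa: float = 200.0,
                  z_wall_offset: float = 0.5,
                  record_stride: int = 10) -> dict:
    """Metadynamics in the space of the path progress variable s only, with
    a stiff one-sided wall constraining the deviation z below ``z_limit``
    A^2 (the wall acts on z although no Gaussians are deposited there).

    The harmonic wall is placed ``z_wall_offset`` inside the limit so the
    thermal penetration depth sqrt(2 kT / kappa) stays within the stated
    constraint rather than straddling it.

    Bias forces reach the atoms through the chain rule
    dV/ds * ds/dx + dW/dz * dz/dx using the path-CV gradients.  Returns the
    bias, a COLVAR-style record (time, s, sigma, z, V) and the final state.
    """
    from . import path_cv
    from .toysim import langevin_step

    bias = BiasState(temperature, delta_t, initial_height, deposit_interval,
                     adaptive_window, width_floor)
    deposit_stride = max(1, int(round(deposit_interval / state.dt)))
    rows = []
    s_hist_t, s_hist = [], []
    disp = path.displacement_set
    cur = state.copy()
    cur.temperature = temperature

    wall_at = z_limit - z_wall_offset

    def bias_force(coords):
        res = path_cv.pcv_eval(coords, path, gradients=True)
        f = np.zeros_like(coords)
        dvds = bias_derivative(bias, res.s_value)
        _, dwdz = z_wall_force(res.z_value, wall_at, z_kappa)
        f[disp] -= dvds * res.grad_s + dwdz * res.grad_z
        return f

    for step in range(n_steps):
        cur = langevin_step(system, cur, 1, bias_force=bias_force)
        t = cur.step_count * cur.dt
        res = path_cv.pcv_eval(cur.positions, path, gradients=False)
        s_hist_t.append(t)
        s_hist.append(res.s_value)
        if (step + 1) % deposit_stride == 0 and t - s_hist_t[0] >= adaptive_window:
            th = np.array(s_hist_t)
            vh = np.array(s_hist)
            width = adaptive_width(th, vh, adaptive_window, width_floor)
            deposit_gaussian(bias, res.s_value, width, time=t)
        if (step + 1) % record_stride == 0:
            rows.append((t, res.s_value, res.sigma, res.z_value,
                         bias_potential(bias, res.s_value)))
    colvar = np.array(rows) if rows else np.empty((0, 5))
    return {"bias": bias, "colvar": colvar, "state": cur}
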