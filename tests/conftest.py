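"""Shared fixtures: analytic benchmark systems, the cage fixture, and the
expensive shared runs (a converged double-well metadynamics run and a
cage egress path) built once per session."""

import warnings

import numpy as np
import pytest

from egresslab import memetic_path, toysim, wt_metad


@pytest.fixture(scope="session")
def dw_system():
    return toysim.make_double_well(4.0, 1.0)


@pytest.fixture(scope="session")
def metad_run(dw_system):
    """Converged well-tempered run on the 4 kcal/mol double well
    (T=300 K, deltaT=3300 K, h0=0.48 kcal/mol every 0.25 ps)."""
    return wt_metad.run_metad_double_well(dw_system, n_steps=5_000_000, seed=3)


@pytest.fixture(scope="session")
def cage():
    return toysim.make_cage_ligand(n_cage=110, cage_radius=10.0,
                                   n_tunnels=1, seed=4)


@pytest.fixture(scope="session")
def cage_state(cage):
    state = toysim.initial_state(cage, seed=104)
    return toysim.langevin_step(cage, state, 400)


@pytest.fixture(scope="session")
def cage_path(cage, cage_state):
    """A complete egress path on the single-tunnel cage, resampled to 10
    near-equidistant nodes."""
    lp = memetic_path.LambdaParams(rng_seed=11)
    cfg = memetic_path.PathSearchConfig(termination_distance=13.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        path = memetic_path.build_path(cage, cage_state, lp, cfg)
    assert path.complete
    return memetic_path.reparameterize_path(path, 10)
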