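"""Memetic path-search tests: the interaction functional, candidate
sampling, the minimizer against a brute-force oracle, biased pulling and
path assembly/reparameterization."""

import warnings

import numpy as np
import pytest

from egresslab import memetic_path, path_cv, toysim
from egresslab.exceptions import ParameterError
from egresslab.memetic_path import (LambdaParams, Path, PathSearchConfig,
                                    Pose, biased_segment, build_path,
                                    lambda_energy, memetic_minimize,
                                    propose_candidates, reparameterize_path)
from egresslab.toysim import AtomSpec, Conformation, System, ThermoState


def pair_system(s_lig=1.0, v_lig=0.5, s_pro=2.0, v_pro=1.0, eps=0.0):
    atoms = [
        AtomSpec(0, "ligand", partial_volume=s_lig, solvation_coefficient=v_lig,
                 lj_epsilon=eps, charge=0.0),
        AtomSpec(1, "protein", partial_volume=s_pro, solvation_coefficient=v_pro,
                 lj_epsilon=eps, charge=0.0),
    ]
    return System(atoms=atoms, rigid_groups=[[0]])


class TestLambdaFunctional:
    def test_zero_distance_gives_pair_height(self):
        sys_ = pair_system()
        conf = Conformation(np.zeros((2, 3)))
        lp = LambdaParams(gaussian_width=1.0, include_gamma=False)
        # h = s_i v_j + s_j v_i = 1*1.0 + 2*0.5 = 2.0, exponent = 0
        assert lambda_energy(sys_, conf, lp) == pytest.approx(2.0)

    def test_unit_separation_worked_example(self):
        sys_ = pair_system()
        conf = Conformation(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        lp = LambdaParams(gaussian_width=1.0, include_gamma=False)
        assert lambda_energy(sys_, conf, lp) == pytest.approx(2.0 * np.exp(-0.5), abs=1e-4)
        assert lambda_energy(sys_, conf, lp) == pytest.approx(1.2131, abs=1e-4)

    def test_far_separation_leaves_only_gamma(self):
        sys_ = pair_system(eps=0.2)
        conf = Conformation(np.array([[0.0, 0, 0], [400.0, 0, 0]]))
        lp_on = LambdaParams(gaussian_width=1.0, include_gamma=True)
        gamma = toysim.potential_energy(sys_, conf)
        assert lambda_energy(sys_, conf, lp_on) == pytest.approx(
            gamma["vdw"] + gamma["coulomb"], abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_vanishes_without_solvation_coefficients(self, seed):
        sys_ = pair_system(v_lig=0.0, v_pro=0.0)
        rng = np.random.default_rng(seed)
        conf = Conformation(rng.normal(scale=3.0, size=(2, 3)))
        lp = LambdaParams(include_gamma=False)
        assert lambda_energy(sys_, conf, lp) == 0.0


class TestProposeCandidates:
    def test_count_and_radius_contract(self):
        lp = LambdaParams(candidate_count=8, sphere_radius=2.0, rng_seed=3)
        prev = Pose(np.array([1.0, 2.0, 3.0]))
        cands = propose_candidates(prev, lp)
        assert len(cands) == 8
        assert np.allclose(cands[0].com, prev.com)
        for c in cands:
            assert np.linalg.norm(c.com - prev.com) <= 2.0 + 1e-12

    def test_deterministic_given_seed(self):
        lp = LambdaParams(candidate_count=6, sphere_radius=2.0, rng_seed=5)
        prev = Pose(np.zeros(3))
        a = propose_candidates(prev, lp)
        b = propose_candidates(prev, lp)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.com, cb.com)
            assert np.array_equal(ca.rotation, cb.rotation)

    def test_sampling_fills_the_sphere(self):
        lp = LambdaParams(candidate_count=10_000, sphere_radius=2.0, rng_seed=1)
        cands = propose_candidates(Pose(np.zeros(3)), lp)
        radii = np.array([np.linalg.norm(c.com) for c in cands[1:]])
        assert radii.max() > 0.99 * 2.0
        # uniform-in-volume: median radius at (1/2)^(1/3) of rho
        assert np.median(radii) == pytest.approx(2.0 * 0.5 ** (1 / 3), rel=0.05)


class TestMemeticMinimize:
    def test_single_candidate_identity(self):
        sys_ = pair_system()
        conf = Conformation(np.array([[0.0, 0, 0], [4.0, 0, 0]]))
        lp = LambdaParams(local_refine_steps=0, include_gamma=False)
        pose = Pose(np.array([0.0, 0, 0]))
        best, val, clash = memetic_minimize(sys_, conf, [pose], lp)
        assert best is pose and not clash
        assert val == pytest.approx(lambda_energy(sys_, conf, lp))

    def test_refinement_never_worse_than_raw(self):
        sys_ = pair_system(eps=0.3)
        conf = Conformation(np.array([[3.0, 1.0, 0], [0.0, 0, 0]]))
        lp = LambdaParams(rng_seed=4, include_gamma=True, gaussian_width=1.0)
        cands = propose_candidates(Pose(np.array([3.0, 1.0, 0])), lp)
        body = np.zeros((1, 3))
        raw = []
        for c in cands:
            cc = conf.coordinates.copy()
            cc[0] = c.apply(body)[0]
            raw.append(lambda_energy(sys_, Conformation(cc), lp))
        _, val, _ = memetic_minimize(sys_, conf, cands, lp)
        assert val <= min(raw) + 1e-12

    def test_matches_exhaustive_grid_search(self):
        """Single ligand atom attracted to an LJ shell around one protein
        atom: the minimizer must find the grid-search optimum of Lambda
        over COM positions to 1e-3 kcal/mol."""
        sys_ = pair_system(eps=0.3)
        start = np.array([4.0, 0.0, 0.0])
        conf = Conformation(np.array([start, [0.0, 0, 0]]))
        lp = LambdaParams(gaussian_width=1.0, include_gamma=True,
                          candidate_count=32, sphere_radius=2.0,
                          local_refine_steps=40, rng_seed=2)
        cands = propose_candidates(Pose(start), lp)
        _, val, _ = memetic_minimize(sys_, conf, cands, lp)
        # oracle: vectorized closed form of Lambda on a 0.05 A COM grid
        ax = np.arange(-7.0, 7.0 + 1e-9, 0.05)
        gx, gy, gz = np.meshgrid(ax, ax, [0.0], indexing="ij")
        r = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)
        r = np.maximum(r, 0.1)
        h = 1.0 * 1.0 + 2.0 * 0.5
        sig, eps = 3.0, 0.3
        lam_grid = (h * np.exp(-r ** 2 / 2.0)
                    + 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6))
        assert val == pytest.approx(float(lam_grid.min()), abs=1e-3)


class TestBiasedSegment:
    def _free_ligand(self):
        atoms = [AtomSpec(i, "ligand") for i in range(2)]
        sys_ = System(atoms=atoms, rigid_groups=[[0, 1]])
        x = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        v = np.zeros((2, 3))
        return sys_, ThermoState(x, v, friction=1.0, dt=0.002, rng_seed=8)

    def test_zero_force_equals_unbiased(self):
        sys_, state = self._free_ligand()
        cfg = PathSearchConfig(segment_steps=200, bias_force_magnitude=0.0,
                               torque_constant=0.0)
        target = Pose(np.array([5.0, 5.0, 0.0]))
        biased = biased_segment(sys_, state, target, cfg)
        unbiased = toysim.langevin_step(sys_, state, 200)
        assert np.allclose(biased.positions, unbiased.positions, atol=1e-12)

    def test_target_equals_current_gives_zero_direction(self):
        # zero velocity and friction so the COM stays on the target: the
        # degenerate bias direction must stay the zero vector (no NaN,
        # no kick), leaving the system exactly at rest
        sys_, state = self._free_ligand()
        state.friction = 0.0
        cfg = PathSearchConfig(segment_steps=100, bias_force_magnitude=50.0,
                               torque_constant=0.0)
        com = state.positions.mean(axis=0)
        biased = biased_segment(sys_, state, Pose(com), cfg)
        assert np.allclose(biased.positions, state.positions, atol=1e-12)
        assert np.all(np.isfinite(biased.velocities))

    def test_strong_pull_moves_along_target_direction(self):
        sys_, state = self._free_ligand()
        cfg = PathSearchConfig(segment_steps=500, bias_force_magnitude=30.0)
        target_dir = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        target = Pose(state.positions.mean(axis=0) + 20.0 * target_dir)
        out = biased_segment(sys_, state, target, cfg)
        disp = out.positions.mean(axis=0) - state.positions.mean(axis=0)
        cosine = disp @ target_dir / np.linalg.norm(disp)
        assert cosine > 0.9


class TestBuildPath:
    def test_first_node_is_bound_state(self, cage, cage_state):
        lp = LambdaParams(rng_seed=11)
        cfg = PathSearchConfig(termination_distance=13.0, max_nodes=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            path = build_path(cage, cage_state, lp, cfg, n_restarts=0)
        assert np.array_equal(path.nodes[0].coordinates, cage_state.positions)

    def test_every_segment_makes_progress(self, cage_path):
        for a, b in zip(cage_path.nodes[:-1], cage_path.nodes[1:]):
            msd = path_cv.msd_displacement(a, b, cage_path.alignment_set,
                                           cage_path.displacement_set)
            assert msd > 0

    def test_search_is_deterministic(self, cage):
        state = toysim.initial_state(cage, seed=104)
        state = toysim.langevin_step(cage, state, 400)
        lp = LambdaParams(rng_seed=21)
        cfg = PathSearchConfig(termination_distance=13.0, max_nodes=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p1 = build_path(cage, state, lp, cfg, n_restarts=0)
            p2 = build_path(cage, state, lp, cfg, n_restarts=0)
        assert p1.n_nodes == p2.n_nodes
        for a, b in zip(p1.nodes, p2.nodes):
            assert np.array_equal(a.coordinates, b.coordinates)


class TestReparameterize:
    def _collinear_path(self, fractions, length=10.0):
        base = np.array([[0.0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4],
                         [0.0, 0, 0]])
        nodes = []
        for f in fractions:
            c = base.copy()
            c[4, 0] = f * length
            nodes.append(Conformation(c))
        return Path(nodes, [0, 1, 2, 3], [4], lambda_value=0.1,
                    mean_neighbor_msd=1.0)

    def test_idempotent_on_equidistant_path(self):
        path = self._collinear_path([0.0, 0.5, 1.0])
        out = reparameterize_path(path, 3, simplify=False)
        for a, b in zip(path.nodes, out.nodes):
            assert np.allclose(a.coordinates, b.coordinates, atol=1e-9)

    def test_arc_length_resampling_moves_middle_node(self):
        path = self._collinear_path([0.0, 0.9, 1.0])
        out = reparameterize_path(path, 3, simplify=False)
        assert out.nodes[1].coordinates[4, 0] == pytest.approx(5.0, abs=1e-9)

    def test_endpoints_byte_identical(self):
        path = self._collinear_path([0.0, 0.3, 0.7, 1.0])
        out = reparameterize_path(path, 5)
        assert np.array_equal(out.nodes[0].coordinates, path.nodes[0].coordinates)
        assert np.array_equal(out.nodes[-1].coordinates, path.nodes[-1].coordinates)

    def test_degenerate_path_rejected(self):
        path = self._collinear_path([0.0, 0.0])
        with pytest.raises(ParameterError, match="degenerate"):
            reparameterize_path(path, 3)

    def test_target_n_precondition(self):
        path = self._collinear_path([0.0, 1.0])
        with pytest.raises(ParameterError):
            reparameterize_path(path, 1)
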