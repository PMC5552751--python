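"""State-decomposition tests: pairwise RMSD, classical MDS, DBSCAN against
a brute-force reference, occupancies, medoids and external assignment."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from egresslab import conf_analysis, toysim
from egresslab.conf_analysis import (DistanceMatrix, assign_external,
                                     basin_occupancy, classical_mds,
                                     dbscan_cluster, decompose_states,
                                     representative_conformer, rmsd_matrix,
                                     subset_rmsd)
from egresslab.exceptions import ParameterError
from egresslab.toysim import Conformation


def brute_force_dbscan(points, eps, min_pts):
    """Textbook DBSCAN: find core points, grow clusters by BFS in index
    order, label the rest noise."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None], axis=2)
    neighbors = [np.where(d[i] <= eps)[0] for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        queue = [i]
        labels[i] = cid
        while queue:
            j = queue.pop(0)
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cid
                    queue.append(k)
        cid += 1
    return labels


@pytest.fixture()
def random_confs():
    rng = np.random.default_rng(3)
    base = rng.normal(scale=4.0, size=(12, 3))
    out = []
    for i in range(6):
        out.append(Conformation(base + rng.normal(scale=0.5, size=base.shape),
                                label=f"f{i}"))
    return out


class TestRMSDMatrix:
    def test_duplicate_frames_have_zero_distance(self, random_confs):
        confs = random_confs + [random_confs[0].copy()]
        dm = rmsd_matrix(confs, np.arange(12))
        assert dm.entries[0, -1] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, random_confs):
        a = random_confs[0]
        rot = Rotation.from_euler("xyz", [10, 60, -30], degrees=True).as_matrix()
        b = Conformation(a.coordinates @ rot.T + [1.0, 2.0, 3.0])
        assert subset_rmsd(a, b, np.arange(12)) < 1e-9

    def test_matches_independent_two_step_oracle(self, random_confs):
        a, b = random_confs[1], random_confs[2]
        idx = np.arange(12)
        ours = subset_rmsd(a, b, idx)
        # oracle: scipy alignment then explicit RMS
        xa = a.coordinates - a.coordinates.mean(0)
        xb = b.coordinates - b.coordinates.mean(0)
        rot, _ = Rotation.align_vectors(xb, xa)
        ref = np.sqrt(np.mean(np.sum((rot.apply(xa) - xb) ** 2, axis=1)))
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_symmetry_and_zero_diagonal(self, random_confs):
        dm = rmsd_matrix(random_confs, np.arange(12))
        assert np.allclose(dm.entries, dm.entries.T, atol=1e-12)
        assert np.all(np.diag(dm.entries) == 0)


class TestClassicalMDS:
    def test_collinear_points_recover_gaps(self):
        d = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
        emb = classical_mds(DistanceMatrix(d), dim=2, normalize=False)
        rec = np.linalg.norm(emb[:, None] - emb[None], axis=2)
        assert np.allclose(rec, d, atol=1e-9)

    def test_identical_frames_collapse(self):
        d = np.zeros((4, 4))
        emb = classical_mds(DistanceMatrix(d), dim=2, normalize=False)
        assert np.allclose(emb, emb[0], atol=1e-12)

    def test_planted_plane_recovered(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(25, 2))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        emb = classical_mds(DistanceMatrix(d), dim=2, normalize=False)
        rec = np.linalg.norm(emb[:, None] - emb[None], axis=2)
        stress = np.sum((rec - d) ** 2) / np.sum(d ** 2)
        assert stress < 1e-6

    def test_normalized_embedding_unit_square(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(10, 2))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        emb = classical_mds(DistanceMatrix(d), dim=2)
        assert emb.min() >= 0.0 and emb.max() <= 1.0
        assert emb.min(axis=0) == pytest.approx([0.0, 0.0])


class TestDBSCAN:
    def test_planted_blobs_two_clusters_no_noise(self):
        rng = np.random.default_rng(5)
        a = rng.normal(scale=0.02, size=(100, 2)) + [0.25, 0.5]
        b = rng.normal(scale=0.02, size=(100, 2)) + [0.75, 0.5]
        labels = dbscan_cluster(np.vstack([a, b]), eps=0.1, min_pts=5)
        assert set(labels) == {0, 1}
        assert np.all(labels[:100] == labels[0])
        assert np.all(labels[100:] == labels[100])

    def test_isolated_point_is_noise(self):
        pts = np.vstack([np.zeros((6, 2)) + np.arange(6)[:, None] * 0.01,
                         [[5.0, 5.0]]])
        labels = dbscan_cluster(pts, eps=0.1, min_pts=5)
        assert labels[-1] == -1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_reference(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.vstack([
            rng.normal(scale=0.05, size=(20, 2)),
            rng.normal(scale=0.05, size=(20, 2)) + [1.0, 0.0],
            rng.uniform(-1, 2, size=(10, 2)),
        ])
        ours = dbscan_cluster(pts, eps=0.15, min_pts=4)
        ref = brute_force_dbscan(pts, eps=0.15, min_pts=4)
        # identical up to cluster relabeling
        assert np.array_equal(ours == -1, ref == -1)
        mapping = {}
        for o, r in zip(ours, ref):
            if o == -1:
                continue
            assert mapping.setdefault(o, r) == r


class TestOccupancyAndMedoids:
    def test_counting_example(self):
        occ = basin_occupancy([0, 0, 0, 1, -1])
        assert occ == {0: 0.6, 1: 0.2, -1: 0.2}

    def test_single_cluster(self):
        assert basin_occupancy([2, 2, 2]) == {2: 1.0}

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(-1, 4, size=137)
        assert sum(basin_occupancy(labels).values()) == pytest.approx(1.0)

    def test_medoid_exhaustive_three_member(self):
        # B (index 1) is central: distances A-B=1, B-C=1, A-C=2
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        med = representative_conformer(DistanceMatrix(d), [0, 0, 0])
        assert med == {0: 1}

    def test_singleton_cluster_is_its_own_medoid(self):
        d = np.array([[0.0, 5.0], [5.0, 0.0]])
        med = representative_conformer(DistanceMatrix(d), [0, 1])
        assert med == {0: 0, 1: 1}


class TestAssignExternal:
    def test_member_frame_assigned_with_zero_distance(self, random_confs):
        labels = [0, 0, 0, 1, 1, -1]
        lab, dist = assign_external(random_confs[3], random_confs, labels,
                                    np.arange(12))
        assert lab == 1 and dist == pytest.approx(0.0, abs=1e-9)

    def test_distance_is_minimum_over_non_noise(self, random_confs):
        labels = [0, 0, 0, 1, 1, -1]
        probe = Conformation(random_confs[0].coordinates + 0.3)
        lab, dist = assign_external(probe, random_confs, labels, np.arange(12))
        ref = min(subset_rmsd(probe, random_confs[i], np.arange(12))
                  for i in range(5))
        assert dist == pytest.approx(ref, abs=1e-12)

    def test_no_clusters_rejected(self, random_confs):
        with pytest.raises(ParameterError):
            assign_external(random_confs[0], random_confs, [-1] * 6,
                            np.arange(12))


class TestPipeline:
    def test_planted_mixture_recovered(self, cage):
        """70/30 closed/open conformer mixture: the MDS+DBSCAN pipeline
        must find two basins with occupancies near the planted fractions
        and medoids separated by more than the intra-family spread."""
        confs, truth = toysim.make_state_families(cage, 70, 30, seed=2)
        subset = cage.environment_indices
        dec = decompose_states(confs, subset, min_pts=5)
        real = sorted((v for k, v in dec.occupancy.items() if k != -1),
                      reverse=True)
        assert len(real) == 2
        assert real[0] == pytest.approx(0.70, abs=0.05)
        assert real[1] == pytest.approx(0.30, abs=0.05)
        # medoid separation across families exceeds the intra-family scale
        meds = list(dec.medoid_index.values())
        inter = subset_rmsd(confs[meds[0]], confs[meds[1]], subset)
        same0 = [i for i, l in enumerate(dec.labels) if l == dec.labels[meds[0]]]
        intra = np.mean([subset_rmsd(confs[meds[0]], confs[i], subset)
                         for i in same0[:10] if i != meds[0]])
        assert inter > intra

    def test_frame_permutation_invariance(self, cage):
        confs, _ = toysim.make_state_families(cage, 20, 10, seed=3)
        subset = cage.environment_indices
        d1 = decompose_states(confs, subset, min_pts=4)
        perm = np.random.default_rng(0).permutation(len(confs))
        d2 = decompose_states([confs[i] for i in perm], subset, min_pts=4)
        occ1 = sorted(d1.occupancy.values())
        occ2 = sorted(d2.occupancy.values())
        assert np.allclose(occ1, occ2)
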