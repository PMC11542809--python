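import numpy as np
import pytest

from circfold import (
    Cluster,
    ConfigError,
    Ensemble,
    Snapshot,
    most_probable_from_tail,
    pairwise_rmsd_matrix,
    pick_centroids,
    qt_cluster,
    select_low_energy,
    snapshot_schedule,
)
from circfold.dynamics import Trajectory
from circfold.ensemble import backbone_mask

from conftest import quaternion_rmsd


class TestSnapshotSchedule:
    def test_production_protocol_count(self):
        sched = snapshot_schedule(100.0, 0.5, 100.0, replicas=10, runs=3)
        assert len(sched) == 15_000

    def test_small_arithmetic(self):
        sched = snapshot_schedule(1.0, 0.5, 10.0, replicas=1, runs=1)
        assert len(sched) == 50
        assert sched[-1][2] == pytest.approx(1.0)

    def test_window_shorter_than_interval(self):
        with pytest.raises(ConfigError):
            snapshot_schedule(0.1, 0.5, 100.0, replicas=1, runs=1)

    def test_count_law_randomized(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            sim = rng.uniform(1, 200)
            frac = rng.uniform(0.05, 1.0)
            interval = rng.uniform(1, 500)
            reps = int(rng.integers(1, 12))
            runs = int(rng.integers(1, 4))
            window = sim * 1e3 * frac
            expected = int(np.floor(window / interval + 1e-9))
            if expected < 1:
                with pytest.raises(ConfigError):
                    snapshot_schedule(sim, frac, interval, reps, runs)
            else:
                got = snapshot_schedule(sim, frac, interval, reps, runs)
                assert len(got) == runs * reps * expected


def _make_ensemble(energies, template):
    snaps = [Snapshot(np.zeros((template.n_beads, 3)) + i, float(e),
                      run_id=0, replica_id=i % 3, time_ns=float(i))
             for i, e in enumerate(energies)]
    return Ensemble(snaps, template)


class TestSelectLowEnergy:
    def test_minimum_selected(self, hairpin):
        _, _, chain, _ = hairpin
        ens = _make_ensemble([5, 4, 3, 2, 1, 0, 9, 8, 7, 6], chain)
        low = select_low_energy(ens, 0.10)
        assert len(low) == 1
        assert low.snapshots[0].potential_energy == 0

    def test_fraction_arithmetic(self, hairpin):
        _, _, chain, _ = hairpin
        ens = _make_ensemble(list(range(200)), chain)
        assert len(select_low_energy(ens, 0.10)) == 20

    def test_energy_separation(self, hairpin):
        _, _, chain, _ = hairpin
        rng = np.random.default_rng(0)
        ens = _make_ensemble(list(rng.normal(size=60)), chain)
        low = select_low_energy(ens, 0.25)
        emax = max(s.potential_energy for s in low.snapshots)
        chosen = {id(s) for s in low.snapshots}
        rest = [s for s in ens.snapshots if id(s) not in chosen]
        assert emax <= min(s.potential_energy for s in rest)

    def test_tie_break_earlier_time(self, hairpin):
        _, _, chain, _ = hairpin
        snaps = [
            Snapshot(np.zeros((chain.n_beads, 3)), 1.0, 0, 0, time_ns=9.0),
            Snapshot(np.zeros((chain.n_beads, 3)), 0.0, 0, 0, time_ns=5.0),
            Snapshot(np.zeros((chain.n_beads, 3)), 1.0, 0, 0, time_ns=2.0),
        ]
        ens = Ensemble(snaps, chain)
        low = select_low_energy(ens, 2 / 3)
        times = sorted(s.time_ns for s in low.snapshots)
        assert times == [2.0, 5.0]

    def test_order_invariance(self, hairpin):
        _, _, chain, _ = hairpin
        rng = np.random.default_rng(1)
        energies = list(rng.normal(size=40))
        ens = _make_ensemble(energies, chain)
        perm = rng.permutation(40)
        shuffled = Ensemble([ens.snapshots[i] for i in perm], chain)
        a = select_low_energy(ens, 0.3)
        b = select_low_energy(shuffled, 0.3)
        ka = sorted((s.potential_energy, s.time_ns) for s in a.snapshots)
        kb = sorted((s.potential_energy, s.time_ns) for s in b.snapshots)
        assert ka == kb

    def test_zero_floor_keeps_one(self, hairpin):
        _, _, chain, _ = hairpin
        ens = _make_ensemble([3.0, 1.0, 2.0], chain)
        with pytest.warns(UserWarning):
            low = select_low_energy(ens, 0.1)
        assert len(low) == 1
        assert low.snapshots[0].potential_energy == 1.0


class TestRmsdMatrix:
    def test_self_zero_and_symmetry(self, hairpin):
        _, _, chain, _ = hairpin
        rng = np.random.default_rng(2)
        structs = [chain.coords + rng.normal(0, 1, chain.coords.shape)
                   for _ in range(4)]
        m = pairwise_rmsd_matrix(structs, backbone_mask(chain))
        assert np.allclose(np.diag(m), 0.0)
        assert np.allclose(m, m.T)

    def test_rotated_copy_is_zero(self, hairpin):
        _, _, chain, _ = hairpin
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        m = pairwise_rmsd_matrix([chain.coords, chain.coords @ q.T + 5.0])
        assert m[0, 1] < 1e-9

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(4)
        structs = [rng.normal(size=(3, 3)) * 4 for _ in range(5)]
        m = pairwise_rmsd_matrix(structs)
        for i in range(5):
            for j in range(i + 1, 5):
                assert m[i, j] == pytest.approx(
                    quaternion_rmsd(structs[i], structs[j]), abs=1e-9)


def _matrix_from_groups(groups, within=1.0, between=100.0):
    n = sum(groups)
    m = np.full((n, n), between, float)
    start = 0
    for g in groups:
        m[start:start + g, start:start + g] = within
        start += g
    np.fill_diagonal(m, 0.0)
    return m


class TestQtCluster:
    def test_single_cluster(self):
        m = _matrix_from_groups([6], within=1.0)
        clusters = qt_cluster(m, 2.0)
        assert len(clusters) == 1 and clusters[0].size == 6

    def test_two_groups_sizes(self):
        m = _matrix_from_groups([6, 4])
        clusters = qt_cluster(m, 2.0)
        assert [c.size for c in clusters] == [6, 4]
        # brute-force neighbor counting confirms the seed of the first
        # cluster has 5 neighbors within the cutoff
        counts = (m <= 2.0).sum(axis=1)
        assert counts[clusters[0].centroid_id] == 6

    def test_all_singletons(self):
        m = _matrix_from_groups([1] * 5, between=50.0)
        clusters = qt_cluster(m, 1.0)
        assert len(clusters) == 5
        assert all(c.size == 1 for c in clusters)

    def test_partition_and_radius_property(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(30, 2)) * 3
        m = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        for cutoff in (0.5, 1.5, 4.0):
            clusters = qt_cluster(m, cutoff)
            members = sorted(i for c in clusters for i in c.member_ids)
            assert members == list(range(30))
            assert sum(c.size for c in clusters) == 30
            for c in clusters:
                assert all(m[c.centroid_id, i] <= cutoff
                           for i in c.member_ids)

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(25, 3))
        m = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        cuts = [0.2, 0.5, 1.0, 2.0, 5.0]
        counts = [len(qt_cluster(m, c)) for c in cuts]
        assert counts == sorted(counts, reverse=True)


class TestPickCentroids:
    def _clusters(self, sizes):
        out = []
        start = 0
        for s in sizes:
            ids = list(range(start, start + s))
            out.append(Cluster(ids, ids[0], s))
            start += s
        return out

    def test_top_five_of_seven(self):
        clusters = self._clusters([9, 8, 7, 6, 5, 4, 3])
        ids = pick_centroids(clusters, 5)
        assert ids == [c.centroid_id for c in clusters[:5]]

    def test_fewer_clusters_warns(self):
        clusters = self._clusters([5, 4, 3])
        with pytest.warns(UserWarning):
            ids = pick_centroids(clusters, 5)
        assert len(ids) == 3

    def test_size_tie_lower_centroid_first(self):
        a = Cluster([4, 5], 4, 2)
        b = Cluster([0, 1], 0, 2)
        ordered = qt_cluster(_matrix_from_groups([2, 2, 2]), 2.0)
        assert [c.centroid_id for c in ordered] \
            == sorted(c.centroid_id for c in ordered)
        ids = pick_centroids([b, a], 2)
        assert ids == [0, 4]

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            pick_centroids([], 5)


def _traj_from_frames(frames):
    frames = np.asarray(frames, float)
    n = len(frames)
    return Trajectory(np.arange(n, dtype=float), frames,
                      np.zeros(n), np.full(n, 300.0))


class TestMostProbableFromTail:
    def test_constant_trajectory(self, hairpin):
        _, _, chain, _ = hairpin
        traj = _traj_from_frames([chain.coords] * 10)
        out = most_probable_from_tail(traj, chain, 0.5, cutoff=2.0)
        assert np.array_equal(out.coords, chain.coords)

    def test_majority_state_wins(self, hairpin):
        _, _, chain, _ = hairpin
        rng = np.random.default_rng(7)
        state_a = chain.coords
        state_b = chain.coords + 200.0
        frames = [state_a + rng.normal(0, 0.05, chain.coords.shape)
                  for _ in range(7)]
        frames += [state_b + rng.normal(0, 0.05, chain.coords.shape)
                   for _ in range(3)]
        traj = _traj_from_frames(frames)
        out = most_probable_from_tail(traj, chain, 1.0, cutoff=2.0)
        assert np.linalg.norm(out.coords.mean(axis=0)
                              - state_a.mean(axis=0)) < 5.0

    def test_tail_fraction_one_uses_all(self, hairpin):
        _, _, chain, _ = hairpin
        frames = [chain.coords + i for i in range(5)]
        traj = _traj_from_frames(frames)
        out = most_probable_from_tail(traj, chain, 1.0, cutoff=100.0)
        assert out.coords.shape == chain.coords.shape
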