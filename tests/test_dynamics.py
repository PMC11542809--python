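import math

import numpy as np
import pytest

from circfold import (
    AnnealSchedule,
    ConfigError,
    SimulationState,
    build_anneal_schedule,
    choose_closure_duration,
    langevin_step,
    make_temperature_ladder,
    remd_exchange_probability,
    run_remd,
)
from circfold.dynamics import (
    ACC_CONV,
    attempt_neighbor_swaps,
    maxwell_velocities,
)
from circfold.forcefield import KB, System, circularize_topology
from circfold.secondary_structure import pair_restraints


def _harmonic_force(k, x0):
    def f(x):
        return -k * (x - x0)
    return f


class TestLangevinStep:
    def test_free_flight(self):
        rng = np.random.default_rng(0)
        v0 = rng.normal(size=(4, 3)) * 1e-3
        state = SimulationState(np.zeros((4, 3)), v0.copy(),
                                np.full(4, 100.0))
        zeros = np.zeros((4, 3))
        state, _ = langevin_step(state, zeros, 1.0, 300.0, 0.0, rng,
                                 force_fn=lambda x: zeros)
        assert np.allclose(state.positions, v0 * 1.0, atol=1e-15)

    def test_symplectic_energy_drift(self):
        """gamma = 0 reduces BAOAB to velocity Verlet: a two-bead harmonic
        oscillator conserves energy to < 1e-3 relative over 1e4 steps."""
        k = 5.0
        masses = np.array([100.0, 100.0])
        x = np.array([[0.0, 0.0, 0.0], [4.5, 0.0, 0.0]])  # b0 = 4.0
        b0 = 4.0

        def force(pos):
            d = pos[1] - pos[0]
            r = np.linalg.norm(d)
            f = 2 * k * (r - b0) * d / r
            return np.array([f, -f])

        def energy(state):
            r = np.linalg.norm(state.positions[1] - state.positions[0])
            return k * (r - b0) ** 2 + state.kinetic_energy()

        rng = np.random.default_rng(0)
        state = SimulationState(x, np.zeros_like(x), masses)
        f = force(x)
        e0 = energy(state)
        for _ in range(10_000):
            state, f = langevin_step(state, f, 1.0, 300.0, 0.0, rng, force)
        assert abs(energy(state) - e0) / abs(e0) < 1e-3

    def test_kinetic_temperature_equipartition(self):
        """30-bead harmonic chain at 300 K: time-averaged kinetic
        temperature within 3 sigma of the thermostat setting."""
        n = 30
        masses = np.full(n, 150.0)
        b0, k = 5.0, 10.0
        x = np.zeros((n, 3))
        x[:, 0] = np.arange(n) * b0

        def force(pos):
            f = np.zeros_like(pos)
            d = pos[1:] - pos[:-1]
            r = np.linalg.norm(d, axis=1)
            g = (2 * k * (r - b0) / r)[:, None] * d
            f[:-1] += g
            f[1:] -= g
            return f

        rng = np.random.default_rng(2024)
        T, gamma, dt = 300.0, 0.01, 1.0
        state = SimulationState(x, maxwell_velocities(masses, T, rng), masses)
        f = force(x)
        temps = []
        for step in range(100_000):
            state, f = langevin_step(state, f, dt, T, gamma, rng, force)
            if step % 20 == 0:
                temps.append(state.kinetic_temperature())
        mean_T = np.mean(temps)
        # 3N dof, instantaneous T is chi-square: var = 2 T^2 / (3 N);
        # correlation time ~ 1/gamma -> effective sample size
        n_eff = len(temps) * 20 * dt / (2 / gamma)
        sigma = T * math.sqrt(2 / (3 * n)) / math.sqrt(n_eff)
        assert abs(mean_T - T) < 3 * sigma + 1.0  # +1 K discretization bias

    def test_determinism(self):
        def run(seed):
            rng = np.random.default_rng(seed)
            state = SimulationState(np.zeros((3, 3)),
                                    np.zeros((3, 3)), np.full(3, 100.0))
            zeros = np.zeros((3, 3))
            for _ in range(100):
                state, _ = langevin_step(state, zeros, 1.0, 300.0, 0.01, rng,
                                         force_fn=lambda x: zeros)
            return state.positions

        assert np.array_equal(run(7), run(7))
        assert not np.array_equal(run(7), run(8))


class TestAnnealSchedule:
    def test_endpoints(self):
        s = build_anneal_schedule(10.0)
        assert s.temperature(0.0) == 500.0
        assert s.restraint_k(0.0) == pytest.approx(0.001)
        assert s.pair_scale(0.0) == 0.01
        assert s.temperature(10.0) == 300.0
        assert s.restraint_k(10.0) == pytest.approx(5.0)
        assert s.pair_scale(10.0) == 1.0

    def test_interpolants(self):
        s = build_anneal_schedule(10.0)
        assert s.temperature(5.0) == pytest.approx(400.0)
        # k is geometric over the ramp window: its midpoint is the
        # geometric mean of the endpoints
        t_mid_ramp = 0.5 * s.ramp_fraction * 10.0
        assert s.restraint_k(t_mid_ramp) == pytest.approx(
            math.sqrt(0.001 * 5.0), rel=1e-9)
        # held at k_hi after the ramp completes
        assert s.restraint_k(0.95 * 10.0) == pytest.approx(5.0)

    def test_monotonicity(self):
        s = build_anneal_schedule(3.0)
        ts = np.linspace(0, 3.0, 301)
        T = [s.temperature(t) for t in ts]
        k = [s.restraint_k(t) for t in ts]
        sc = [s.pair_scale(t) for t in ts]
        assert all(a >= b for a, b in zip(T, T[1:]))
        assert all(a <= b for a, b in zip(k, k[1:]))
        assert all(a <= b for a, b in zip(sc, sc[1:]))

    def test_invalid(self):
        with pytest.raises(ConfigError):
            build_anneal_schedule(-1.0)
        with pytest.raises(ConfigError):
            build_anneal_schedule(1.0, scales=())


class TestClosureDuration:
    @pytest.mark.parametrize("sep,expected", [
        (0.0, 10.0), (20.0, 10.0), (200.0, 50.0), (500.0, 50.0),
        (110.0, 30.0),  # midpoint of the linear ramp 20->200 Å, 10->50 ns
    ])
    def test_ramp(self, sep, expected):
        assert choose_closure_duration(sep) == pytest.approx(expected)


class TestExchange:
    def test_equal_energies(self):
        assert remd_exchange_probability(-50.0, -50.0, 280.0, 460.0) == 1.0

    def test_favorable_swap_capped(self):
        assert remd_exchange_probability(-90.0, -100.0, 280.0, 460.0) == 1.0

    def test_unfavorable_swap(self):
        beta = lambda T: 1.0 / (KB * T)
        expected = math.exp(-(beta(280.0) - beta(460.0)) * 10.0)
        assert remd_exchange_probability(-100.0, -90.0, 280.0, 460.0) \
            == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(8.8e-4, rel=0.02)

    def test_swap_conserves_configuration_multiset(self):
        rng = np.random.default_rng(5)
        n_rep = 6
        states = [SimulationState(rng.normal(size=(4, 3)),
                                  rng.normal(size=(4, 3)) * 1e-3,
                                  np.full(4, 100.0)) for _ in range(n_rep)]
        forces = [rng.normal(size=(4, 3)) for _ in range(n_rep)]
        energies = list(rng.normal(size=n_rep) * 10)
        temps = [300.0 * 1.1 ** m for m in range(n_rep)]
        before = sorted(tuple(s.positions.ravel()) for s in states)
        for parity in (0, 1, 0, 1):
            attempt_neighbor_swaps(states, forces, energies, temps, parity,
                                   rng)
        after = sorted(tuple(s.positions.ravel()) for s in states)
        assert before == after

    def test_empirical_acceptance_matches_analytic(self):
        """Two replicas of a single bead in a harmonic well: the observed
        swap frequency agrees with the mean Metropolis probability."""
        temps = [300.0, 500.0]
        k_spring = 2.0
        masses = np.full(1, 120.0)

        def force(pos):
            return -2 * k_spring * pos

        def energy(pos):
            return float(k_spring * np.sum(pos ** 2))

        rng = np.random.default_rng(99)
        ex_rng = np.random.default_rng(1234)
        states = [SimulationState(np.zeros((1, 3)),
                                  maxwell_velocities(masses, T, rng), masses,
                                  temperature_set=T) for T in temps]
        forces = [force(s.positions) for s in states]
        attempts = 0
        accepted = 0
        p_sum = 0.0
        p_var = 0.0
        for cycle in range(3000):
            for _ in range(10):
                for m, T in enumerate(temps):
                    states[m], forces[m] = langevin_step(
                        states[m], forces[m], 1.0, T, 0.02, rng, force)
            energies = [energy(s.positions) for s in states]
            p = remd_exchange_probability(energies[0], energies[1],
                                          temps[0], temps[1])
            p_sum += p
            p_var += p * (1 - p)
            n_before = states[0].positions.copy()
            attempt_neighbor_swaps(states, forces, energies, temps, 0, ex_rng)
            attempts += 1
            if not np.array_equal(states[0].positions, n_before):
                accepted += 1
        emp = accepted / attempts
        mean_p = p_sum / attempts
        sigma = math.sqrt(p_var) / attempts
        assert abs(emp - mean_p) < 3 * sigma + 1e-3


class TestLadder:
    def test_default_endpoints(self):
        ladder = make_temperature_ladder()
        assert ladder.temperatures[0] == pytest.approx(280.0)
        assert ladder.temperatures[-1] == pytest.approx(460.0)
        assert ladder.n_replicas == 10

    def test_two_rungs(self):
        ladder = make_temperature_ladder(2)
        assert list(ladder.temperatures) == pytest.approx([280.0, 460.0])

    def test_geometric_spacing_closed_form(self):
        ladder = make_temperature_ladder(10)
        expected = 280.0 * (460.0 / 280.0) ** (1 / 9)
        assert ladder.temperatures[1] == pytest.approx(expected, rel=1e-12)

    def test_too_few_rungs(self):
        with pytest.raises(ConfigError):
            make_temperature_ladder(1)


@pytest.fixture(scope="module")
def tiny_circular():
    from circfold import fixtures, map_to_cg
    from circfold.secondary_structure import parse_dotbracket
    seq, db, s = fixtures.build_hairpin(3, 4)
    chain = circularize_topology(map_to_cg(s))
    return chain, parse_dotbracket(seq, db, circular=True)


class TestRunRemd:
    def test_determinism_bitwise(self, tiny_circular, params):
        chain, pt = tiny_circular
        from circfold.dynamics import ReplicaLadder
        ladder = ReplicaLadder((300.0, 380.0), exchange_interval=50)
        out1 = run_remd([chain], ladder, 300, [3], params, pt,
                        snapshot_interval_steps=100)
        out2 = run_remd([chain], ladder, 300, [3], params, pt,
                        snapshot_interval_steps=100)
        for t1, t2 in zip(out1[0], out2[0]):
            assert np.array_equal(t1.coords, t2.coords)
            assert np.array_equal(t1.potential, t2.potential)

    def test_single_temperature_is_plain_langevin(self, tiny_circular, params):
        chain, pt = tiny_circular
        from circfold.dynamics import ReplicaLadder
        ladder = ReplicaLadder((320.0,), exchange_interval=50)
        out = run_remd([chain], ladder, 200, [4], params, pt,
                       snapshot_interval_steps=100)
        assert len(out) == 1 and len(out[0]) == 1
        assert out[0][0].n_frames == 2

    def test_provenance(self, tiny_circular, params):
        chain, pt = tiny_circular
        from circfold.dynamics import ReplicaLadder
        ladder = ReplicaLadder((300.0, 380.0), exchange_interval=50)
        out = run_remd([chain, chain], ladder, 100, [3, 4], params, pt,
                       snapshot_interval_steps=50)
        assert [[t.replica_id for t in run] for run in out] == [[0, 1], [0, 1]]
        assert [run[0].run_id for run in out] == [0, 1]
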