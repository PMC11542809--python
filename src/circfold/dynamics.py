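"""Langevin dynamics, simulated-annealing end closure, and replica exchange.

Units: Å, fs, kcal/mol, g/mol, K.  A single conversion constant
``ACC_CONV`` turns force/mass (kcal/mol/Å per g/mol) into acceleration
(Å/fs²); the Boltzmann constant is 1.9872e-3 kcal/mol/K.

The integrator is the BAOAB splitting of Langevin dynamics (kick /
drift / Ornstein-Uhlenbeck / drift / kick), which gives robust
configurational sampling at the 1 fs timestep used throughout.

End closure pulls the two termini of a linear chain together with a
harmonic restraint whose force constant ramps geometrically from 0.001 to
5.0 kcal/mol/Å² while the temperature anneals linearly from 500 K to 300 K
and the base-pairing interactions are staged through scale factors
0.01 / 0.1 / 1.0 (unfold, then refold).

Replica exchange runs a ladder of temperatures (default 10 rungs,
280-460 K, geometric spacing) with Metropolis neighbor swaps attempted at a
fixed interval, alternating even/odd neighbor pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError, SimulationBlowupError, TopologyError
from .forcefield import (
    KB,
    ClosureRestraint,
    EnergyBreakdown,
    ForceFieldParams,
    System,
    default_params,
)
from .secondary_structure import PairTable, pair_restraints
from .structure_io import CGChain

#: (kcal/mol/Å) / (g/mol) -> Å/fs²
ACC_CONV = 4.184e-4


# ---------------------------------------------------------------------------
# State and schedule containers
# ---------------------------------------------------------------------------

@dataclass
class SimulationState:
    positions: np.ndarray   # (B, 3) Å
    velocities: np.ndarray  # (B, 3) Å/fs
    masses: np.ndarray      # (B,) g/mol
    time: float = 0.0       # fs
    temperature_set: float = 300.0  # K

    def __post_init__(self) -> None:
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions/velocities shape mismatch")
        if self.masses.shape != (self.positions.shape[0],):
            raise ValueError("masses shape mismatch")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    def kinetic_energy(self) -> float:
        """Kinetic energy in kcal/mol."""
        return float(0.5 * np.sum(self.masses[:, None] * self.velocities ** 2)
                     / ACC_CONV)

    def kinetic_temperature(self) -> float:
        """Instantaneous kinetic temperature, 2 KE / (3 N k_B)."""
        n = self.positions.shape[0]
        return 2.0 * self.kinetic_energy() / (3.0 * n * KB)


def maxwell_velocities(masses: np.ndarray, T: float,
                       rng: np.random.Generator) -> np.ndarray:
    sigma = np.sqrt(KB * T * ACC_CONV / masses)
    return rng.normal(size=(len(masses), 3)) * sigma[:, None]


@dataclass
class AnnealSchedule:
    """Time program of the end-closure stage.

    Temperature is linear in time (T_hi -> T_lo), the restraint force
    constant geometric (k_lo -> k_hi), and the pairing scale piecewise
    constant over equal stages.
    """

    duration_ns: float
    T_hi: float = 500.0
    T_lo: float = 300.0
    k_lo: float = 0.001
    k_hi: float = 5.0
    scales: Tuple[float, ...] = (0.01, 0.1, 1.0)
    #: fraction of the run over which k ramps; k holds at k_hi afterwards so
    #: the structure-selection window (the trailing 10%) samples under the
    #: full-strength restraint
    ramp_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.duration_ns <= 0:
            raise ConfigError("schedule duration must be positive")
        if self.T_hi < self.T_lo:
            raise ConfigError("T_hi must be >= T_lo")
        if not self.scales:
            raise ConfigError("pair-scale stages must be non-empty")
        if list(self.scales) != sorted(self.scales):
            raise ConfigError("pair-scale stages must be non-decreasing")
        if not (0 < self.ramp_fraction <= 1):
            raise ConfigError("ramp_fraction must be in (0, 1]")

    def temperature(self, t_ns: float) -> float:
        f = min(max(t_ns / self.duration_ns, 0.0), 1.0)
        return self.T_hi + (self.T_lo - self.T_hi) * f

    def restraint_k(self, t_ns: float) -> float:
        f = min(max(t_ns / (self.ramp_fraction * self.duration_ns), 0.0), 1.0)
        return self.k_lo * (self.k_hi / self.k_lo) ** f

    def pair_scale(self, t_ns: float) -> float:
        f = min(max(t_ns / self.duration_ns, 0.0), 1.0)
        stage = min(int(f * len(self.scales)), len(self.scales) - 1)
        return self.scales[stage]


def build_anneal_schedule(duration_ns: float, T_hi: float = 500.0,
                          T_lo: float = 300.0, k_lo: float = 0.001,
                          k_hi: float = 5.0,
                          scales: Sequence[float] = (0.01, 0.1, 1.0),
                          ramp_fraction: float = 0.8) -> AnnealSchedule:
    """Anneal program: linear T over the run, geometric (log-linear)
    restraint k over the first ``ramp_fraction`` of the run (held at k_hi
    afterwards), pairing scale staged over equal thirds."""
    return AnnealSchedule(duration_ns, T_hi, T_lo, k_lo, k_hi, tuple(scales),
                          ramp_fraction)


def choose_closure_duration(end_separation: float) -> float:
    """Closure-run length in ns as a function of the end separation.

    Linear ramp from 10 ns at 20 Å to 50 ns at 200 Å, clamped to [10, 50].
    """
    if end_separation < 0:
        raise ValueError("separation must be non-negative")
    return float(np.clip(10.0 + (end_separation - 20.0) * 40.0 / 180.0,
                         10.0, 50.0))


@dataclass
class ReplicaLadder:
    temperatures: Tuple[float, ...]
    exchange_interval: int = 1000  # steps (1 ps at dt = 1 fs)

    def __post_init__(self) -> None:
        ts = list(self.temperatures)
        if len(ts) < 1 or ts != sorted(ts) or len(set(ts)) != len(ts):
            raise ConfigError("ladder temperatures must be strictly increasing")
        if self.exchange_interval < 1:
            raise ConfigError("exchange interval must be >= 1 step")

    @property
    def n_replicas(self) -> int:
        return len(self.temperatures)


def make_temperature_ladder(n: int = 10, T_min: float = 280.0,
                            T_max: float = 460.0,
                            exchange_interval: int = 1000) -> ReplicaLadder:
    """Geometric ladder T_m = T_min (T_max/T_min)^(m/(n-1))."""
    if n < 2:
        raise ConfigError("a ladder needs at least 2 rungs")
    if T_max <= T_min:
        raise ConfigError("T_max must exceed T_min")
    temps = tuple(T_min * (T_max / T_min) ** (m / (n - 1)) for m in range(n))
    return ReplicaLadder(temps, exchange_interval)


def remd_exchange_probability(E_i: float, E_j: float,
                              T_i: float, T_j: float) -> float:
    """Metropolis probability for swapping neighboring replicas,
    p = min(1, exp[(beta_i - beta_j)(E_i - E_j)])."""
    if T_i <= 0 or T_j <= 0:
        raise ValueError("temperatures must be positive")
    beta_i = 1.0 / (KB * T_i)
    beta_j = 1.0 / (KB * T_j)
    arg = (beta_i - beta_j) * (E_i - E_j)
    if arg >= 0:
        return 1.0
    return math.exp(arg)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Frames of one simulation (coordinates + potential energies)."""

    times_ns: np.ndarray            # (F,)
    coords: np.ndarray              # (F, B, 3)
    potential: np.ndarray           # (F,) kcal/mol
    temperatures: np.ndarray        # (F,) set temperature at frame time
    run_id: int = 0
    replica_id: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.times_ns)

    def energy_tsv(self) -> str:
        lines = ["time_ns\tpotential\ttemperature\trun\treplica"]
        for t, e, T in zip(self.times_ns, self.potential, self.temperatures):
            lines.append(f"{t:.6f}\t{e:.6f}\t{T:.3f}\t{self.run_id}\t{self.replica_id}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Integrator
# ---------------------------------------------------------------------------

def _check_finite(forces: np.ndarray) -> None:
    if not np.all(np.isfinite(forces)):
        bad = int(np.argmax(~np.isfinite(forces).all(axis=1)))
        mx = float(np.nanmax(np.abs(forces)))
        raise SimulationBlowupError(
            f"non-finite force (max |f| = {mx:.3g}) at bead {bad}; "
            "reduce the timestep or the restraint ramp rate"
        )


def langevin_step(state: SimulationState, forces: np.ndarray, dt: float,
                  T: float, gamma: float, rng: np.random.Generator,
                  force_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None
                  ) -> Tuple[SimulationState, np.ndarray]:
    """One BAOAB Langevin update.

    ``forces`` are the forces at the current positions; ``force_fn`` supplies
    the recomputed forces after the drift (when omitted, the step reuses the
    input forces, which downgrades the final kick to the old geometry).
    Returns the new state together with the forces at the new positions so
    the caller can chain steps with one evaluation per step.
    """
    if dt <= 0 or T < 0 or gamma < 0:
        raise ValueError("dt > 0, T >= 0, gamma >= 0 required")
    _check_finite(forces)
    m = state.masses[:, None]
    v = state.velocities + 0.5 * dt * forces * ACC_CONV / m
    x = state.positions + 0.5 * dt * v
    if gamma > 0:
        c1 = math.exp(-gamma * dt)
        c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
        sigma = np.sqrt(KB * T * ACC_CONV / state.masses)[:, None]
        v = c1 * v + c2 * sigma * rng.normal(size=v.shape)
    x = x + 0.5 * dt * v
    if not np.all(np.isfinite(x)):
        raise SimulationBlowupError("non-finite coordinates after drift")
    new_forces = force_fn(x) if force_fn is not None else forces
    _check_finite(new_forces)
    v = v + 0.5 * dt * new_forces * ACC_CONV / m
    new_state = SimulationState(x, v, state.masses, state.time + dt, T)
    return new_state, new_forces


# ---------------------------------------------------------------------------
# End closure
# ---------------------------------------------------------------------------

def run_end_closure(chain: CGChain, pt: PairTable, schedule: AnnealSchedule,
                    seed: int, params: Optional[ForceFieldParams] = None,
                    dt_fs: float = 1.0, gamma: float = 0.01,
                    n_frames: int = 200, cluster_cutoff: float = 2.0
                    ) -> Tuple[Trajectory, CGChain]:
    """Simulated-annealing end closure of a linear chain.

    Runs Langevin dynamics under the annealing schedule with the harmonic
    end restraint (bead P of nt 1 to bead S of nt N) ramped from k_lo to
    k_hi.  Returns the trajectory and the most probable conformation of the
    final 10% of frames (largest cluster centroid), which seeds the
    subsequent structure-prediction stage.
    """
    if chain.circular:
        raise TopologyError("end closure expects a linear chain")
    if chain.n_nt < 2:
        raise TopologyError("need at least 2 nt to attach the end restraint")
    from .ensemble import most_probable_from_tail  # deferred: avoid cycle

    params = params or default_params()
    system = System(chain, params, pair_restraints(pt), exclude_end_pair=True)
    rng = np.random.default_rng(seed)
    n_steps = max(1, int(round(schedule.duration_ns * 1e6 / dt_fs)))
    frame_every = max(1, n_steps // n_frames)

    state = SimulationState(chain.coords.copy(),
                            maxwell_velocities(chain.masses,
                                               schedule.temperature(0.0), rng),
                            chain.masses.copy(), 0.0,
                            schedule.temperature(0.0))
    t_ns = 0.0
    eb, forces = system.energy_forces(state.positions,
                                      schedule.pair_scale(0.0),
                                      schedule.restraint_k(0.0))
    times, coords, pots, temps = [], [], [], []
    for step in range(n_steps):
        t_ns = step * dt_fs * 1e-6
        T = schedule.temperature(t_ns)
        k = schedule.restraint_k(t_ns)
        scale = schedule.pair_scale(t_ns)
        holder = {}

        def force_fn(x, _k=k, _s=scale, _h=holder):
            e, f = system.energy_forces(x, _s, _k)
            _h["eb"] = e
            return f

        state, forces = langevin_step(state, forces, dt_fs, T, gamma, rng,
                                      force_fn)
        if (step + 1) % frame_every == 0:
            times.append((step + 1) * dt_fs * 1e-6)
            coords.append(state.positions.copy())
            pots.append(holder["eb"].total)
            temps.append(T)
    traj = Trajectory(np.array(times), np.array(coords), np.array(pots),
                      np.array(temps))
    closed = most_probable_from_tail(traj, chain, tail_fraction=0.10,
                                     cutoff=cluster_cutoff)
    return traj, closed


# ---------------------------------------------------------------------------
# Replica exchange
# ---------------------------------------------------------------------------

def attempt_neighbor_swaps(states: List[SimulationState],
                           forces: List[np.ndarray],
                           energies: List[float],
                           temperatures: Sequence[float],
                           parity: int,
                           rng: np.random.Generator) -> List[int]:
    """Metropolis exchange attempts between neighboring temperature rungs.

    Visits rung pairs (parity, parity+1), (parity+2, parity+3), ...; accepted
    swaps exchange configurations between rungs (velocities rescaled by
    sqrt(T_new/T_old)).  The multiset of configurations across rungs is
    conserved.  Returns the list of lower-rung indices whose swap was
    accepted.
    """
    accepted = []
    n = len(states)
    for m in range(parity, n - 1, 2):
        p = remd_exchange_probability(energies[m], energies[m + 1],
                                      temperatures[m], temperatures[m + 1])
        if rng.random() < p:
            states[m], states[m + 1] = states[m + 1], states[m]
            forces[m], forces[m + 1] = forces[m + 1], forces[m]
            energies[m], energies[m + 1] = energies[m + 1], energies[m]
            ratio = math.sqrt(temperatures[m] / temperatures[m + 1])
            states[m].velocities *= ratio
            states[m + 1].velocities /= ratio
            states[m].temperature_set = temperatures[m]
            states[m + 1].temperature_set = temperatures[m + 1]
            accepted.append(m)
    return accepted


def run_remd(starts: Sequence[CGChain], ladder: ReplicaLadder, steps: int,
             seeds: Sequence[int], params: Optional[ForceFieldParams] = None,
             pt: Optional[PairTable] = None, dt_fs: float = 1.0,
             gamma: float = 0.01, snapshot_interval_steps: int = 1000
             ) -> List[List[Trajectory]]:
    """Replica-exchange MD from each starting structure.

    Every start spawns an independent run covering the full temperature
    ladder.  Neighbor swaps are attempted every ``exchange_interval`` steps,
    alternating even/odd rung pairs; accepted swaps exchange configurations
    between temperature rungs (velocities are rescaled by sqrt(T_new/T_old)),
    which is the rung-major view of "temperatures swap, configurations
    persist".  Returns, per run, one trajectory per temperature rung with
    provenance (run id, replica id).
    """
    if not starts:
        raise ConfigError("need at least one starting structure")
    if len(seeds) < len(starts):
        raise ConfigError("need one seed per starting structure")
    params = params or default_params()
    results: List[List[Trajectory]] = []
    for run_id, (start, seed) in enumerate(zip(starts, seeds)):
        if not start.circular:
            raise TopologyError("REMD expects circularized chains")
        pairs = pair_restraints(pt) if pt is not None else None
        system = System(start, params, pairs)
        n_rep = ladder.n_replicas
        rng = np.random.default_rng([int(seed), run_id])
        ex_rng = np.random.default_rng([int(seed), run_id, 7919])
        states = []
        forces = []
        for m, T in enumerate(ladder.temperatures):
            st = SimulationState(start.coords.copy(),
                                 maxwell_velocities(start.masses, T,
                                                    np.random.default_rng([int(seed), run_id, m])),
                                 start.masses.copy(), 0.0, T)
            _, f = system.energy_forces(st.positions, params.pair_scale, None)
            states.append(st)
            forces.append(f)
        rngs = [np.random.default_rng([int(seed), run_id, 104729 + m])
                for m in range(n_rep)]
        frames: List[List[tuple]] = [[] for _ in range(n_rep)]
        energies = [system.energy_forces(states[m].positions,
                                         params.pair_scale, None)[0].total
                    for m in range(n_rep)]
        swap_parity = 0
        for step in range(steps):
            for m in range(n_rep):
                holder = {}

                def force_fn(x, _h=holder):
                    e, f = system.energy_forces(x, params.pair_scale, None)
                    _h["eb"] = e
                    return f

                states[m], forces[m] = langevin_step(
                    states[m], forces[m], dt_fs, ladder.temperatures[m],
                    gamma, rngs[m], force_fn)
                energies[m] = holder["eb"].total
            if (step + 1) % ladder.exchange_interval == 0 and n_rep > 1:
                attempt_neighbor_swaps(states, forces, energies,
                                       ladder.temperatures, swap_parity,
                                       ex_rng)
                swap_parity = 1 - swap_parity
            if (step + 1) % snapshot_interval_steps == 0:
                t_ns = (step + 1) * dt_fs * 1e-6
                for m in range(n_rep):
                    frames[m].append((t_ns, states[m].positions.copy(),
                                      energies[m], ladder.temperatures[m]))
        run_trajs = []
        for m in range(n_rep):
            if frames[m]:
                ts, cs, es, Ts = zip(*frames[m])
            else:
                ts, cs, es, Ts = (), (), (), ()
            run_trajs.append(Trajectory(
                np.array(ts), np.array(cs).reshape(len(cs), -1, 3)
                if cs else np.zeros((0, start.n_beads, 3)),
                np.array(es), np.array(Ts), run_id=run_id, replica_id=m))
        results.append(run_trajs)
    return results
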