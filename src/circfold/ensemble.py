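"""Conformational-ensemble bookkeeping: snapshot collection, low-energy
selection, RMSD clustering and centroid extraction.

The production protocol collects snapshots from the trailing half of every
replica of every run at a fixed interval (100 ns simulations, 10 replicas,
3 runs, 100 ps interval -> 15,000 snapshots), submits the 10% with the
lowest potential energies to greedy quality-threshold clustering on
backbone-bead RMSD, and reports the centroids of the largest clusters as
the predicted models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError
from .rebuild import kabsch_superpose
from .structure_io import CGChain


@dataclass
class Snapshot:
    coords: np.ndarray      # (B, 3)
    potential_energy: float
    run_id: int
    replica_id: int
    time_ns: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.potential_energy):
            raise ValueError("snapshot energy must be finite")


@dataclass
class Ensemble:
    snapshots: List[Snapshot]
    chain_template: CGChain

    def __post_init__(self) -> None:
        nb = self.chain_template.n_beads
        for s in self.snapshots:
            if s.coords.shape != (nb, 3):
                raise ValueError("snapshot does not conform to the template")

    def __len__(self) -> int:
        return len(self.snapshots)

    def index_tsv(self) -> str:
        lines = ["snapshot\trun\treplica\ttime_ns\tpotential"]
        for i, s in enumerate(self.snapshots):
            lines.append(f"{i}\t{s.run_id}\t{s.replica_id}\t{s.time_ns:.6f}"
                         f"\t{s.potential_energy:.6f}")
        return "\n".join(lines) + "\n"


@dataclass
class Cluster:
    member_ids: List[int]
    centroid_id: int
    size: int

    def __post_init__(self) -> None:
        if self.centroid_id not in self.member_ids:
            raise ValueError("centroid must be a member of its cluster")
        if self.size != len(self.member_ids):
            raise ValueError("cluster size inconsistent with members")


# ---------------------------------------------------------------------------
# Snapshot schedule
# ---------------------------------------------------------------------------

def snapshot_schedule(sim_time_ns: float, collect_fraction: float = 0.5,
                      interval_ps: float = 100.0, replicas: int = 10,
                      runs: int = 3) -> List[Tuple[int, int, float]]:
    """Enumerate (run, replica, time_ns) collection points.

    The collection window is the trailing ``collect_fraction`` of the
    simulation; times step by ``interval_ps`` and end exactly at
    ``sim_time_ns``.  Count = runs * replicas * floor(window / interval).
    """
    if not (0 < collect_fraction <= 1):
        raise ConfigError("collect_fraction must be in (0, 1]")
    if interval_ps <= 0:
        raise ConfigError("interval must be positive")
    window_ps = sim_time_ns * 1e3 * collect_fraction
    n_per = int(np.floor(window_ps / interval_ps + 1e-9))
    if n_per < 1:
        raise ConfigError(
            f"collection window ({window_ps} ps) shorter than the interval "
            f"({interval_ps} ps)")
    end_ps = sim_time_ns * 1e3
    times = [(end_ps - (n_per - 1 - k) * interval_ps) * 1e-3
             for k in range(n_per)]
    out = []
    for run in range(runs):
        for rep in range(replicas):
            for t in times:
                out.append((run, rep, t))
    return out


# ---------------------------------------------------------------------------
# Selection and clustering
# ---------------------------------------------------------------------------

def select_low_energy(ensemble: Ensemble, fraction: float = 0.10) -> Ensemble:
    """The floor(fraction * n) snapshots with the lowest potential energies.

    Ties at the cutoff break by earlier time, then lower replica id.  When
    the floor comes out to zero the single lowest-energy snapshot is kept
    (with a warning).
    """
    if not (0 < fraction <= 1):
        raise ConfigError("fraction must be in (0, 1]")
    n = len(ensemble)
    if n == 0:
        raise ConfigError("ensemble is empty")
    k = int(np.floor(fraction * n))
    if k == 0:
        warnings.warn("top-fraction selection came out empty; keeping the "
                      "single lowest-energy snapshot", stacklevel=2)
        k = 1
    order = sorted(range(n), key=lambda i: (
        ensemble.snapshots[i].potential_energy,
        ensemble.snapshots[i].time_ns,
        ensemble.snapshots[i].replica_id,
        ensemble.snapshots[i].run_id,
    ))
    chosen = sorted(order[:k])
    return Ensemble([ensemble.snapshots[i] for i in chosen],
                    ensemble.chain_template)


def backbone_mask(chain: CGChain) -> np.ndarray:
    """Boolean mask selecting the P and S beads (backbone fold identity)."""
    mask = np.zeros(chain.n_beads, dtype=bool)
    for i in range(chain.n_nt):
        mask[5 * i] = True
        mask[5 * i + 1] = True
    return mask


def pairwise_rmsd_matrix(structures: Sequence[np.ndarray],
                         bead_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Symmetric matrix of Kabsch-minimized RMSDs over the masked beads."""
    arrs = [np.asarray(s, dtype=float) for s in structures]
    if bead_mask is not None:
        arrs = [a[bead_mask] for a in arrs]
    n = len(arrs)
    shape = arrs[0].shape if n else None
    for a in arrs:
        if a.shape != shape:
            raise ValueError("structures differ in bead count")
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = kabsch_superpose(arrs[i], arrs[j]).rmsd
    return m


def qt_cluster(matrix: np.ndarray, cutoff: float) -> List[Cluster]:
    """Greedy quality-threshold clustering.

    Repeatedly seed on the unassigned structure with the most unassigned
    neighbors within the cutoff (ties -> lowest index); the seed becomes the
    cluster centroid and its in-cutoff neighbors the members.  Clusters are
    returned ordered by size (descending), ties by centroid index.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    if cutoff <= 0:
        raise ConfigError("cutoff must be positive")
    n = matrix.shape[0]
    unassigned = np.ones(n, dtype=bool)
    clusters: List[Cluster] = []
    while np.any(unassigned):
        idx = np.nonzero(unassigned)[0]
        sub = matrix[np.ix_(idx, idx)] <= cutoff
        counts = sub.sum(axis=1)  # includes self
        seed_pos = int(np.argmax(counts))  # argmax takes the lowest index on ties
        seed = int(idx[seed_pos])
        members = [int(i) for i in idx[sub[seed_pos]]]
        clusters.append(Cluster(sorted(members), seed, len(members)))
        unassigned[members] = False
    clusters.sort(key=lambda c: (-c.size, c.centroid_id))
    return clusters


def pick_centroids(clusters: Sequence[Cluster], n_models: int = 5) -> List[int]:
    """Centroid ids of the up-to-``n_models`` largest clusters."""
    if not clusters:
        raise ConfigError("no clusters to pick centroids from")
    sizes = [c.size for c in clusters]
    if sizes != sorted(sizes, reverse=True):
        raise ValueError("clusters must be ordered by size (descending)")
    if len(clusters) < n_models:
        warnings.warn(
            f"only {len(clusters)} clusters available; returning that many "
            f"models instead of {n_models}", stacklevel=2)
    return [c.centroid_id for c in clusters[:n_models]]


def most_probable_from_tail(trajectory, template: CGChain,
                            tail_fraction: float = 0.10,
                            cutoff: float = 2.0) -> CGChain:
    """Centroid of the largest cluster over the trailing frames.

    Implements the selection of the most probable conformation from the last
    ``tail_fraction`` of a trajectory by quality-threshold clustering on
    backbone RMSD.
    """
    n = trajectory.n_frames
    k = int(np.floor(n * tail_fraction))
    if n == 0 or (k < 1 and tail_fraction < 1):
        if n >= 1:
            k = 1
        else:
            raise ConfigError("trajectory tail is empty")
    k = max(1, min(n, k if tail_fraction < 1 else n))
    tail = trajectory.coords[n - k:]
    mask = backbone_mask(template)
    m = pairwise_rmsd_matrix(list(tail), mask)
    clusters = qt_cluster(m, cutoff)
    best = clusters[0]
    return template.with_coords(tail[best.centroid_id])


def cluster_report_tsv(clusters: Sequence[Cluster],
                       ensemble: Ensemble) -> str:
    lines = ["cluster\tsize\tcentroid_snapshot\tmean_energy"]
    for ci, c in enumerate(clusters):
        mean_e = float(np.mean([ensemble.snapshots[i].potential_energy
                                for i in c.member_ids]))
        lines.append(f"{ci}\t{c.size}\t{c.centroid_id}\t{mean_e:.6f}")
    return "\n".join(lines) + "\n"
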