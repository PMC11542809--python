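"""Four-stage circular-RNA 3D prediction workflow.

1. **Input preparation** — read the sequence, the circular secondary
   structure (dot-bracket whose string ends meet at the back-splicing
   junction) and one or more all-atom models of the linear counterpart; map
   them to the five-bead CG representation, classify the BSJ, audit the
   inputs for locally irrational topology.
2. **End closure** — simulated-annealing Langevin run per initial structure
   with the ramped harmonic end restraint and staged pairing
   (unfold-refold); the most probable tail conformation seeds stage 3.
3. **Structure prediction** — circularize the topology, run
   temperature-ladder REMD from each closed start, collect snapshots from
   the trailing window, keep the lowest-energy tenth, cluster by backbone
   RMSD and take the largest clusters' centroids.
4. **Model refinement** — rebuild all-atom coordinates by fragment matching,
   run the geometry cleanup, write PDB models, reports and a manifest.

A ``time_scale`` factor shrinks every duration (and the snapshot interval
identically) so the whole pipeline runs at desk scale for testing; the
production profile is time_scale = 1 with the full 100 ns / 10 replica /
3 run protocol.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dynamics import (
    Trajectory,
    build_anneal_schedule,
    choose_closure_duration,
    make_temperature_ladder,
    run_end_closure,
    run_remd,
)
from .ensemble import (
    Ensemble,
    Snapshot,
    backbone_mask,
    cluster_report_tsv,
    pairwise_rmsd_matrix,
    pick_centroids,
    qt_cluster,
    select_low_energy,
)
from .errors import CircfoldError, ConfigError
from .fixtures import FIXTURE_KINDS, generate_fixture
from .forcefield import circularize_topology, default_params
from .rebuild import build_fragment_library, geometry_cleanup, rebuild_all_atom
from .secondary_structure import classify_bsj, parse_dotbracket
from .structure_io import AllAtomStructure, CGChain, map_to_cg, read_pdb, write_pdb
from .topology_qc import TopologyReport, qc_report

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_CONFIG_SCHEMA: Dict[str, Dict[str, object]] = {
    "input": {"sequence": None, "structure": None, "pdbs": None},
    "simulation": {
        "remd_time_ns": 100.0,
        "time_scale": 1.0,
        "replicas": 10,
        "t_min": 280.0,
        "t_max": 460.0,
        "runs": 3,
        "exchange_interval_steps": 1000,
        "dt_fs": 1.0,
        "friction_per_fs": 0.01,
    },
    "closure": {
        "b0": 3.8,
        "k_lo": 0.001,
        "k_hi": 5.0,
        "t_hi": 500.0,
        "t_lo": 300.0,
    },
    "ensemble": {
        "collect_fraction": 0.5,
        "snapshot_interval_ps": 100.0,
        "low_energy_fraction": 0.1,
        "cluster_cutoff": 5.0,
    },
    "output": {"n_models": 5, "directory": "circfold_out", "qc": True},
    "seeds": {"master": 0},
}


@dataclass
class RunConfig:
    sequence_path: str
    structure_path: str
    pdb_paths: List[str]
    remd_time_ns: float = 100.0
    time_scale: float = 1.0
    replicas: int = 10
    t_min: float = 280.0
    t_max: float = 460.0
    runs: int = 3
    exchange_interval_steps: int = 1000
    dt_fs: float = 1.0
    friction_per_fs: float = 0.01
    closure_b0: float = 3.8
    closure_k_lo: float = 0.001
    closure_k_hi: float = 5.0
    closure_t_hi: float = 500.0
    closure_t_lo: float = 300.0
    collect_fraction: float = 0.5
    snapshot_interval_ps: float = 100.0
    low_energy_fraction: float = 0.1
    cluster_cutoff: float = 5.0
    n_models: int = 5
    output_dir: str = "circfold_out"
    qc: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_models < 1:
            raise ConfigError("n_models must be >= 1")
        if not self.pdb_paths:
            raise ConfigError("at least one initial PDB is required")
        if self.replicas < 1 or self.runs < 1:
            raise ConfigError("replicas and runs must be >= 1")
        if self.time_scale <= 0 or self.remd_time_ns <= 0:
            raise ConfigError("time scale and simulation time must be positive")
        if not (0 < self.collect_fraction <= 1):
            raise ConfigError("collect_fraction must be in (0, 1]")
        if self.cluster_cutoff <= 0:
            raise ConfigError("cluster cutoff must be positive")


def load_config(path) -> RunConfig:
    """Parse and validate a TOML run configuration (fails on unknown keys)."""
    import tomllib

    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"cannot parse config: {exc}") from exc
    for section, keys in raw.items():
        if section not in _CONFIG_SCHEMA:
            raise ConfigError(f"unknown config section {section!r}")
        for key in keys:
            if key not in _CONFIG_SCHEMA[section]:
                raise ConfigError(
                    f"unknown config key {section}.{key!r}")
    inp = raw.get("input", {})
    for req in ("sequence", "structure", "pdbs"):
        if req not in inp:
            raise ConfigError(f"missing required config key input.{req}")
    sim = raw.get("simulation", {})
    clo = raw.get("closure", {})
    ens = raw.get("ensemble", {})
    out = raw.get("output", {})
    seeds = raw.get("seeds", {})
    cfg = RunConfig(
        sequence_path=str(inp["sequence"]),
        structure_path=str(inp["structure"]),
        pdb_paths=[str(p) for p in inp["pdbs"]],
        remd_time_ns=float(sim.get("remd_time_ns", 100.0)),
        time_scale=float(sim.get("time_scale", 1.0)),
        replicas=int(sim.get("replicas", 10)),
        t_min=float(sim.get("t_min", 280.0)),
        t_max=float(sim.get("t_max", 460.0)),
        runs=int(sim.get("runs", 3)),
        exchange_interval_steps=int(sim.get("exchange_interval_steps", 1000)),
        dt_fs=float(sim.get("dt_fs", 1.0)),
        friction_per_fs=float(sim.get("friction_per_fs", 0.01)),
        closure_b0=float(clo.get("b0", 3.8)),
        closure_k_lo=float(clo.get("k_lo", 0.001)),
        closure_k_hi=float(clo.get("k_hi", 5.0)),
        closure_t_hi=float(clo.get("t_hi", 500.0)),
        closure_t_lo=float(clo.get("t_lo", 300.0)),
        collect_fraction=float(ens.get("collect_fraction", 0.5)),
        snapshot_interval_ps=float(ens.get("snapshot_interval_ps", 100.0)),
        low_energy_fraction=float(ens.get("low_energy_fraction", 0.1)),
        cluster_cutoff=float(ens.get("cluster_cutoff", 5.0)),
        n_models=int(out.get("n_models", 5)),
        output_dir=str(out.get("directory", "circfold_out")),
        qc=bool(out.get("qc", True)),
        seed=int(seeds.get("master", 0)),
    )
    cfg.validate()
    return cfg


@dataclass
class RunManifest:
    stage_timings: Dict[str, float] = field(default_factory=dict)
    seed_registry: Dict[str, int] = field(default_factory=dict)
    artifacts: Dict[str, List[str]] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)

    def add_artifact(self, stage: str, path: str) -> None:
        self.artifacts.setdefault(stage, []).append(str(path))

    def all_files(self) -> List[str]:
        return [p for paths in self.artifacts.values() for p in paths]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Input reading
# ---------------------------------------------------------------------------

def read_sequence_file(path) -> str:
    """Plain or FASTA sequence file -> uppercase RNA sequence."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    seq = "".join(ln for ln in lines if ln and not ln.startswith(">"))
    return seq.upper().replace("T", "U")


def read_structure_file(path) -> str:
    """Dot-bracket file (optionally FASTA-style) -> structure string."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    for ln in lines:
        if ln and not ln.startswith(">") and set(ln) <= set("()."):
            return ln
    raise ConfigError(f"no dot-bracket line found in {path}")


# ---------------------------------------------------------------------------
# The workflow
# ---------------------------------------------------------------------------

def predict(config: RunConfig) -> Tuple[List[str], RunManifest, TopologyReport]:
    """Run the full four-stage prediction; returns (model paths, manifest,
    combined QC report of the emitted models)."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed_registry={"master": config.seed})
    params = default_params()

    # --- stage 1: input preparation ---------------------------------------
    t0 = time.time()
    sequence = read_sequence_file(config.sequence_path)
    db = read_structure_file(config.structure_path)
    pt_circ = parse_dotbracket(sequence, db, circular=True)
    pt_lin = parse_dotbracket(sequence, db, circular=False)
    initials: List[CGChain] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for p in config.pdb_paths:
            structure = read_pdb(Path(p).read_text())
            if len(structure) != len(sequence):
                raise ConfigError(
                    f"initial structure {p} has {len(structure)} residues but "
                    f"the sequence has {len(sequence)} nt")
            if structure.sequence != sequence:
                raise ConfigError(
                    f"initial structure {p} sequence differs from the input "
                    "sequence")
            initials.append(map_to_cg(structure, circular=False))
    manifest.warnings += [str(w.message) for w in caught]
    if len(db) != len(sequence):
        raise ConfigError("sequence/structure length mismatch")
    bsj = classify_bsj(pt_circ)
    input_qc: Optional[TopologyReport] = None
    if config.qc:
        input_reports = [qc_report(c, pt_lin) for c in initials]
        input_qc = TopologyReport(
            [f for r in input_reports for f in r.findings])
        path = out_dir / "qc_input.tsv"
        path.write_text(input_qc.findings_tsv())
        manifest.add_artifact("input", path)
    manifest.stage_timings["input_preparation"] = time.time() - t0

    # --- stage 2: end closure ---------------------------------------------
    t0 = time.time()
    closed: List[CGChain] = []
    rng_root = np.random.SeedSequence([config.seed, 1])
    for i, chain in enumerate(initials):
        sep = chain.end_separation()
        dur = choose_closure_duration(sep) * config.time_scale
        schedule = build_anneal_schedule(
            dur, config.closure_t_hi, config.closure_t_lo,
            config.closure_k_lo, config.closure_k_hi)
        seed = int(rng_root.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        manifest.seed_registry[f"closure_{i}"] = seed
        traj, closed_chain = run_end_closure(
            chain, pt_circ, schedule, seed, params,
            dt_fs=config.dt_fs, gamma=config.friction_per_fs,
            cluster_cutoff=config.cluster_cutoff)
        path = out_dir / f"closure_{i}_energy.tsv"
        path.write_text(traj.energy_tsv())
        manifest.add_artifact("end_closure", path)
        closed.append(closed_chain)
    manifest.stage_timings["end_closure"] = time.time() - t0

    # --- stage 3: structure prediction ------------------------------------
    t0 = time.time()
    starts = [circularize_topology(c) for c in closed]
    n_runs = min(config.runs, len(starts))
    if n_runs < config.runs:
        manifest.warnings.append(
            f"only {len(starts)} starting structures available; running "
            f"{n_runs} REMD runs instead of {config.runs}")
    ladder = make_temperature_ladder(
        config.replicas, config.t_min, config.t_max,
        config.exchange_interval_steps) if config.replicas > 1 else None
    steps = max(1, int(round(config.remd_time_ns * config.time_scale * 1e6
                             / config.dt_fs)))
    snap_steps = max(1, int(round(config.snapshot_interval_ps
                                  * config.time_scale * 1e3 / config.dt_fs)))
    seeds = []
    for r in range(n_runs):
        s = int(np.random.SeedSequence([config.seed, 2, r])
                .generate_state(1)[0] % (2 ** 31))
        seeds.append(s)
        manifest.seed_registry[f"remd_run_{r}"] = s
    if ladder is None:
        from .dynamics import ReplicaLadder
        ladder = ReplicaLadder((config.t_min,), config.exchange_interval_steps)
    runs = run_remd(starts[:n_runs], ladder, steps, seeds, params, pt_circ,
                    dt_fs=config.dt_fs, gamma=config.friction_per_fs,
                    snapshot_interval_steps=snap_steps)

    template = starts[0]
    window_start = steps * (1.0 - config.collect_fraction) * config.dt_fs * 1e-6
    snapshots: List[Snapshot] = []
    for run_trajs in runs:
        for traj in run_trajs:
            for f in range(traj.n_frames):
                if traj.times_ns[f] > window_start + 1e-12:
                    snapshots.append(Snapshot(
                        traj.coords[f], float(traj.potential[f]),
                        traj.run_id, traj.replica_id,
                        float(traj.times_ns[f])))
    if not snapshots:
        raise CircfoldError("no snapshots collected; increase the simulation "
                            "time or reduce the snapshot interval")
    ensemble = Ensemble(snapshots, template)
    path = out_dir / "ensemble_index.tsv"
    path.write_text(ensemble.index_tsv())
    manifest.add_artifact("structure_prediction", path)

    low = select_low_energy(ensemble, config.low_energy_fraction)
    matrix = pairwise_rmsd_matrix([s.coords for s in low.snapshots],
                                  backbone_mask(template))
    clusters = qt_cluster(matrix, config.cluster_cutoff)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        centroid_ids = pick_centroids(clusters, config.n_models)
    manifest.warnings += [str(w.message) for w in caught]
    path = out_dir / "clusters.tsv"
    path.write_text(cluster_report_tsv(clusters, low))
    manifest.add_artifact("structure_prediction", path)
    manifest.stage_timings["structure_prediction"] = time.time() - t0

    # --- stage 4: model refinement ----------------------------------------
    t0 = time.time()
    lib = build_fragment_library()
    model_paths: List[str] = []
    model_findings = []
    models_dir = out_dir / "models"
    models_dir.mkdir(exist_ok=True)
    for rank, cid in enumerate(centroid_ids, start=1):
        cg_model = template.with_coords(low.snapshots[cid].coords)
        rebuilt = rebuild_all_atom(cg_model, lib)
        cleaned = geometry_cleanup(rebuilt, circular=True)
        path = models_dir / f"model_{rank:02d}.pdb"
        path.write_text(write_pdb(cleaned))
        manifest.add_artifact("model_refinement", path)
        model_paths.append(str(path))
        if config.qc:
            shipped_cg = map_to_cg(cleaned, circular=True)
            model_findings.append(qc_report(shipped_cg, pt_circ))
    model_qc = TopologyReport(
        [f for r in model_findings for f in r.findings])
    if config.qc:
        path = out_dir / "qc_models.tsv"
        path.write_text(model_qc.findings_tsv())
        manifest.add_artifact("model_refinement", path)
    manifest.stage_timings["model_refinement"] = time.time() - t0

    summary = {
        "sequence_length": len(sequence),
        "bsj_class": bsj.value,
        "n_models": len(model_paths),
        "input_defects": input_qc.total if input_qc else None,
        "model_defects": model_qc.total if config.qc else None,
    }
    path = out_dir / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest.add_artifact("summary", path)
    manifest_path = out_dir / "manifest.json"
    manifest.add_artifact("summary", manifest_path)
    manifest_path.write_text(manifest.to_json())
    return model_paths, manifest, model_qc


# ---------------------------------------------------------------------------
# Fixture writing (CLI support)
# ---------------------------------------------------------------------------

def write_fixture(kind: str, out_dir, **params) -> List[str]:
    """Generate a fixture and write sequence / dot-bracket / PDB files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq, db, structure = generate_fixture(kind, **params)
    stem = kind.replace(":", "_")
    paths = []
    p = out / f"{stem}.fasta"
    p.write_text(f">{stem}\n{seq}\n")
    paths.append(str(p))
    p = out / f"{stem}.db"
    p.write_text(db + "\n")
    paths.append(str(p))
    if isinstance(structure, CGChain):
        from .rebuild import build_fragment_library, rebuild_all_atom
        structure = rebuild_all_atom(structure, build_fragment_library())
    p = out / f"{stem}.pdb"
    p.write_text(write_pdb(structure))
    paths.append(str(p))
    return paths
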