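"""Surrogate coarse-grained energy/force model.

The energy is a sum of harmonic bonds and angles, cosine torsions, a
Gaussian-well base-pairing attraction between the Watson-Crick-edge beads of
restrained pairs, a purely repulsive (WCA-style) excluded-volume term, and an
optional harmonic end-closure restraint between bead P of nucleotide 1 and
bead S of nucleotide N:

    E_bond     = sum k_b (b - b0)^2
    E_angle    = sum k_th (theta - theta0)^2
    E_torsion  = sum k_phi (1 + cos(n phi - delta)),  delta = n phi0 - pi
    E_pairing  = pair_scale * sum -eps_p exp(-(r - r_p)^2 / (2 sigma_p^2))
    E_ev       = sum_{r < r_ev} eps_ev [ (r_ev/r)^12 - 2 (r_ev/r)^6 + 1 ]
    E_restraint= k (d - b0)^2,  d = |P_1 - S_N|,  b0 = 3.8 Å

``pair_scale`` multiplies only the pairing component; the end-closure
protocol stages it through 0.01 / 0.1 / 1.0.  Equilibrium geometry values
(b0, theta0, phi0) were fitted once from the ideal-helix fixture and are
stored in the versioned parameter file ``data/forcefield_v1.yaml``.

Circular topology simply extends every bonded-term family across the
(N, 1) backbone edge with the same parameters as interior connections.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import GeometryError, TopologyError
from .secondary_structure import PairTable, pair_restraints
from .structure_io import CGChain

KB = 1.9872e-3  # Boltzmann constant, kcal/mol/K

# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BondParam:
    k: float   # kcal/mol/Å^2
    b0: float  # Å


@dataclass(frozen=True)
class AngleParam:
    k: float       # kcal/mol/rad^2
    theta0: float  # rad


@dataclass(frozen=True)
class TorsionParam:
    k: float     # kcal/mol
    n: int       # periodicity
    phi0: float  # rad; the minimum (delta = n*phi0 - pi)


@dataclass(frozen=True)
class PairWell:
    eps: float    # kcal/mol
    r0: float     # Å
    sigma: float  # Å


@dataclass
class ForceFieldParams:
    """Full parameter set; keys follow the bonded-term naming of
    :func:`bonded_terms` (base-specific terms carry a ``:X`` suffix)."""

    bonds: Dict[str, BondParam]
    angles: Dict[str, AngleParam]
    torsions: Dict[str, TorsionParam]
    pairing: Dict[str, PairWell]  # WC / wobble / noncanonical
    r_ev: float = 3.5
    eps_ev: float = 1.0
    pair_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.r_ev <= 0:
            raise ValueError("r_ev must be positive")
        if self.eps_ev < 0 or self.pair_scale <= 0:
            raise ValueError("eps_ev >= 0 and pair_scale > 0 required")
        for p in self.bonds.values():
            if p.k < 0:
                raise ValueError("bond k must be >= 0")
        for p in self.angles.values():
            if p.k < 0:
                raise ValueError("angle k must be >= 0")


@dataclass
class ClosureRestraint:
    """Harmonic end-closure restraint E = k (d - b0)^2 between bead P of the
    first nucleotide and bead S of the last nucleotide."""

    k: float
    b0: float = 3.8

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("restraint force constant must be >= 0")


@dataclass
class EnergyBreakdown:
    bond: float = 0.0
    angle: float = 0.0
    torsion: float = 0.0
    pairing: float = 0.0
    excluded_volume: float = 0.0
    restraint: float = 0.0

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.torsion + self.pairing
                + self.excluded_volume + self.restraint)


def closure_restraint_energy(d: float, k: float, b0: float = 3.8) -> float:
    """Energy of the end-closure restraint, k (d - b0)^2."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    if k < 0:
        raise ValueError("force constant must be non-negative")
    return k * (d - b0) ** 2


# ---------------------------------------------------------------------------
# Bonded topology
# ---------------------------------------------------------------------------

def bonded_terms(sequence: str, circular: bool) -> Dict[str, List[tuple]]:
    """Enumerate the bonded-term lists of a CG chain.

    Returns flat bead indices (5 per nucleotide, order P,S,B1,B2,B3) with a
    parameter key per term.  When ``circular``, every family wraps across the
    (N, 1) backbone edge with the same keys as interior connections.
    """
    n = len(sequence)
    bonds: List[tuple] = []
    angles: List[tuple] = []
    torsions: List[tuple] = []
    for i in range(n):
        x = sequence[i]
        P, S, B1, B2, B3 = (5 * i + k for k in range(5))
        bonds += [
            (P, S, "PS"),
            (S, B1, f"SB1:{x}"),
            (B1, B2, f"B1B2:{x}"),
            (B2, B3, f"B2B3:{x}"),
            (B3, B1, f"B3B1:{x}"),
        ]
        angles += [
            (P, S, B1, f"PSB1:{x}"),
            (S, B1, B2, f"SB1B2:{x}"),
            (S, B1, B3, f"SB1B3:{x}"),
        ]
        torsions.append((P, S, B1, B2, f"CHI:{x}"))
        has_next = i < n - 1 or circular
        if has_next:
            j = (i + 1) % n
            Pn, Sn = 5 * j, 5 * j + 1
            bonds.append((S, Pn, "SP"))
            angles += [
                (P, S, Pn, "PSP"),
                (B1, S, Pn, f"B1SP:{x}"),
                (S, Pn, Sn, "SPS"),
            ]
            torsions.append((P, S, Pn, Sn, "PSPS"))
        if i < n - 2 or (circular and n > 2):
            j = (i + 1) % n
            j2 = (i + 2) % n
            torsions.append((5 * i + 1, 5 * j, 5 * j + 1, 5 * j2, "SPSP"))
    return {"bonds": bonds, "angles": angles, "torsions": torsions}


def circularize_topology(chain: CGChain) -> CGChain:
    """Mark a linear chain circular, wiring the wrap-around bonded terms.

    The bonded-term lists are derived from the ``circular`` flag, so the
    operation is idempotent; re-circularizing only warns and never doubles
    terms.  Single-nucleotide chains cannot be closed.
    """
    if chain.n_nt < 2:
        raise TopologyError("cannot circularize a chain of fewer than 2 nt")
    if chain.circular:
        warnings.warn("chain is already circular; topology unchanged", stacklevel=2)
        return chain
    return CGChain(chain.sequence, chain.coords.copy(), chain.masses.copy(),
                   circular=True)


# ---------------------------------------------------------------------------
# Compiled system
# ---------------------------------------------------------------------------

class System:
    """A CG chain compiled against a parameter set for fast evaluation.

    Precomputes index arrays for every energy term; ``energy_forces`` then
    evaluates the full analytic energy and gradient in vectorized numpy.
    """

    def __init__(self, chain: CGChain, params: ForceFieldParams,
                 pairs: Optional[Sequence[Tuple[int, int, str]]] = None,
                 restraint_b0: float = 3.8, exclude_end_pair: bool = False):
        self.chain = chain
        self.params = params
        n_beads = chain.n_beads
        terms = bonded_terms(chain.sequence, chain.circular)

        def key_lookup(table, key, what):
            if key not in table:
                raise KeyError(f"missing {what} parameter {key!r}")
            return table[key]

        b = terms["bonds"]
        self.bond_idx = np.array([[t[0], t[1]] for t in b], dtype=int)
        self.bond_k = np.array([key_lookup(params.bonds, t[2], "bond").k for t in b])
        self.bond_b0 = np.array([key_lookup(params.bonds, t[2], "bond").b0 for t in b])

        a = terms["angles"]
        self.angle_idx = np.array([[t[0], t[1], t[2]] for t in a], dtype=int)
        self.angle_k = np.array([key_lookup(params.angles, t[3], "angle").k for t in a])
        self.angle_t0 = np.array([key_lookup(params.angles, t[3], "angle").theta0 for t in a])

        t = terms["torsions"]
        self.tors_idx = np.array([[q[0], q[1], q[2], q[3]] for q in t], dtype=int)
        self.tors_k = np.array([key_lookup(params.torsions, q[4], "torsion").k for q in t])
        self.tors_n = np.array([key_lookup(params.torsions, q[4], "torsion").n for q in t])
        self.tors_delta = np.array([
            key_lookup(params.torsions, q[4], "torsion").n
            * key_lookup(params.torsions, q[4], "torsion").phi0 - math.pi
            for q in t
        ])

        if pairs:
            self.pair_idx = np.array(
                [[CGChain.bead_index(i, "B1"), CGChain.bead_index(j, "B1")]
                 for i, j, _ in pairs], dtype=int)
            wells = [params.pairing[cls] for _, _, cls in pairs]
            self.pair_eps = np.array([w.eps for w in wells])
            self.pair_r0 = np.array([w.r0 for w in wells])
            self.pair_sig = np.array([w.sigma for w in wells])
        else:
            self.pair_idx = np.zeros((0, 2), dtype=int)
            self.pair_eps = self.pair_r0 = self.pair_sig = np.zeros(0)

        # excluded-volume pair list: all bead pairs more than 2 bonded edges
        # apart (standard 1-2/1-3 exclusion)
        adj = [set() for _ in range(n_beads)]
        for i, j, _ in b:
            adj[i].add(j)
            adj[j].add(i)
        excluded = np.zeros((n_beads, n_beads), dtype=bool)
        np.fill_diagonal(excluded, True)
        if exclude_end_pair:
            # the closure restraint drives P1 and S_N to bonded range; they
            # become bonded (hence excluded) after circularization anyway
            i_end = CGChain.bead_index(1, "P")
            j_end = CGChain.bead_index(chain.n_nt, "S")
            excluded[i_end, j_end] = excluded[j_end, i_end] = True
        for i in range(n_beads):
            for j in adj[i]:
                excluded[i, j] = True
                for k in adj[j]:
                    excluded[i, k] = True
        iu, ju = np.triu_indices(n_beads, k=1)
        keep = ~excluded[iu, ju]
        self.ev_i = iu[keep]
        self.ev_j = ju[keep]

        self.restraint_i = CGChain.bead_index(1, "P")
        self.restraint_j = CGChain.bead_index(chain.n_nt, "S")
        self.restraint_b0 = restraint_b0

    # -- evaluation ---------------------------------------------------------

    def energy_forces(self, coords: np.ndarray, pair_scale: Optional[float] = None,
                      restraint_k: Optional[float] = None
                      ) -> Tuple[EnergyBreakdown, np.ndarray]:
        x = np.asarray(coords, dtype=float)
        scale = self.params.pair_scale if pair_scale is None else pair_scale
        F = np.zeros_like(x)
        eb = EnergyBreakdown()

        # bonds
        d = x[self.bond_idx[:, 0]] - x[self.bond_idx[:, 1]]
        r = np.linalg.norm(d, axis=1)
        if np.any(r < 1e-8):
            bad = int(np.argmin(r))
            raise GeometryError(
                f"zero-length bond between beads {self.bond_idx[bad]}"
            )
        dr = r - self.bond_b0
        eb.bond = float(np.sum(self.bond_k * dr * dr))
        g = (2.0 * self.bond_k * dr / r)[:, None] * d
        np.add.at(F, self.bond_idx[:, 0], -g)
        np.add.at(F, self.bond_idx[:, 1], g)

        # angles
        i, j, k = self.angle_idx.T
        u = x[i] - x[j]
        v = x[k] - x[j]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        c = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
        s = np.sqrt(np.maximum(1.0 - c * c, 1e-14))
        theta = np.arccos(c)
        dth = theta - self.angle_t0
        eb.angle = float(np.sum(self.angle_k * dth * dth))
        coef = 2.0 * self.angle_k * dth
        dthi = (c[:, None] * uh - vh) / (nu * s)[:, None]
        dthk = (c[:, None] * vh - uh) / (nv * s)[:, None]
        np.add.at(F, i, -coef[:, None] * dthi)
        np.add.at(F, k, -coef[:, None] * dthk)
        np.add.at(F, j, coef[:, None] * (dthi + dthk))

        # torsions
        a_, b_, c_, d_ = self.tors_idx.T
        b1 = x[b_] - x[a_]
        b2 = x[c_] - x[b_]
        b3 = x[d_] - x[c_]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        m1 = np.cross(n1, b2 / nb2[:, None])
        xx = np.sum(n1 * n2, axis=1)
        yy = np.sum(m1 * n2, axis=1)
        phi = np.arctan2(yy, xx)
        arg = self.tors_n * phi - self.tors_delta
        eb.torsion = float(np.sum(self.tors_k * (1.0 + np.cos(arg))))
        dEdphi = -self.tors_k * self.tors_n * np.sin(arg)
        # dphi/dx for this atan2 sign convention (checked against central
        # differences): fa = |b2|/|n1|^2 n1, fd = -|b2|/|n2|^2 n2,
        # fb = -(1+p) fa + q fd, fc = p fa - (1+q) fd.
        sq1 = np.sum(n1 * n1, axis=1)
        sq2 = np.sum(n2 * n2, axis=1)
        fa = (nb2 / sq1)[:, None] * n1
        fd = -(nb2 / sq2)[:, None] * n2
        p = (np.sum(b1 * b2, axis=1) / (nb2 * nb2))[:, None]
        q = (np.sum(b3 * b2, axis=1) / (nb2 * nb2))[:, None]
        fb = -(1.0 + p) * fa + q * fd
        fc = p * fa - (1.0 + q) * fd
        np.add.at(F, a_, -dEdphi[:, None] * fa)
        np.add.at(F, b_, -dEdphi[:, None] * fb)
        np.add.at(F, c_, -dEdphi[:, None] * fc)
        np.add.at(F, d_, -dEdphi[:, None] * fd)

        # pairing (Gaussian well between B1 beads, scaled)
        if len(self.pair_idx):
            d = x[self.pair_idx[:, 0]] - x[self.pair_idx[:, 1]]
            r = np.linalg.norm(d, axis=1)
            z = (r - self.pair_r0) / self.pair_sig
            e = -self.pair_eps * np.exp(-0.5 * z * z)
            eb.pairing = float(scale * np.sum(e))
            dEdr = scale * (-e) * z / self.pair_sig
            g = (dEdr / r)[:, None] * d
            np.add.at(F, self.pair_idx[:, 0], -g)
            np.add.at(F, self.pair_idx[:, 1], g)

        # excluded volume (WCA-style repulsion below r_ev)
        if len(self.ev_i):
            d = x[self.ev_i] - x[self.ev_j]
            r2 = np.sum(d * d, axis=1)
            r_ev = self.params.r_ev
            close = r2 < r_ev * r_ev
            if np.any(close):
                di = d[close]
                r = np.sqrt(r2[close])
                s6 = (r_ev / r) ** 6
                eb.excluded_volume = float(
                    self.params.eps_ev * np.sum(s6 * s6 - 2.0 * s6 + 1.0))
                dEdr = self.params.eps_ev * (-12.0 * s6 * s6 + 12.0 * s6) / r
                g = (dEdr / r)[:, None] * di
                np.add.at(F, self.ev_i[close], -g)
                np.add.at(F, self.ev_j[close], g)

        # end-closure restraint
        if restraint_k is not None and restraint_k > 0:
            d = x[self.restraint_i] - x[self.restraint_j]
            r = float(np.linalg.norm(d))
            if r > 1e-12:
                eb.restraint = restraint_k * (r - self.restraint_b0) ** 2
                g = 2.0 * restraint_k * (r - self.restraint_b0) * d / r
                F[self.restraint_i] -= g
                F[self.restraint_j] += g
        return eb, F


# ---------------------------------------------------------------------------
# Spec-level convenience operations
# ---------------------------------------------------------------------------

def compute_energy(chain: CGChain, params: ForceFieldParams,
                   restraint: Optional[ClosureRestraint] = None,
                   pair_table: Optional[PairTable] = None) -> EnergyBreakdown:
    """Energy breakdown of one conformation (see module docstring for terms)."""
    pairs = pair_restraints(pair_table) if pair_table is not None else None
    sys_ = System(chain, params, pairs,
                  restraint.b0 if restraint else 3.8,
                  exclude_end_pair=restraint is not None)
    eb, _ = sys_.energy_forces(chain.coords,
                               restraint_k=restraint.k if restraint else None)
    return eb


def compute_forces(chain: CGChain, params: ForceFieldParams,
                   restraint: Optional[ClosureRestraint] = None,
                   pair_table: Optional[PairTable] = None) -> np.ndarray:
    """Analytic forces (negative energy gradient), kcal/mol/Å per bead."""
    pairs = pair_restraints(pair_table) if pair_table is not None else None
    sys_ = System(chain, params, pairs,
                  restraint.b0 if restraint else 3.8,
                  exclude_end_pair=restraint is not None)
    _, f = sys_.energy_forces(chain.coords,
                              restraint_k=restraint.k if restraint else None)
    return f


# ---------------------------------------------------------------------------
# Default parameters
# ---------------------------------------------------------------------------

_DEFAULT_STIFFNESS = {
    "bond_k": 20.0,    # kcal/mol/Å^2
    "angle_k": 10.0,   # kcal/mol/rad^2
    "torsion_k": 1.0,  # kcal/mol
}
_DEFAULT_PAIR_EPS = {"WC": 4.0, "wobble": 2.5, "noncanonical": 2.0}


def fit_default_params() -> ForceFieldParams:
    """Measure equilibrium geometry from the ideal-helix fixture.

    Every bonded b0/theta0/phi0 is the value realized in a single-strand
    ideal helix containing all four bases; the pairing well minimum is the
    Watson-Crick-edge bead distance across the fixture duplex.  Stiffnesses
    and the excluded-volume/pairing strengths are the documented defaults.
    This is deterministic and is the generator of ``data/forcefield_v1.yaml``.
    """
    from . import fixtures
    from .structure_io import map_to_cg

    seq = "ACGUACGU"
    helix = map_to_cg(fixtures.build_single_helix(seq))
    x = helix.coords
    terms = bonded_terms(seq, circular=False)

    def dist(i, j):
        return float(np.linalg.norm(x[i] - x[j]))

    def ang(i, j, k):
        u = x[i] - x[j]
        v = x[k] - x[j]
        c = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
        return math.acos(max(-1.0, min(1.0, c)))

    def tors(i, j, k, l):
        b1, b2, b3 = x[j] - x[i], x[k] - x[j], x[l] - x[k]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        return math.atan2(float(m1 @ n2), float(n1 @ n2))

    bond_vals: Dict[str, List[float]] = {}
    for i, j, key in terms["bonds"]:
        bond_vals.setdefault(key, []).append(dist(i, j))
    angle_vals: Dict[str, List[float]] = {}
    for i, j, k, key in terms["angles"]:
        angle_vals.setdefault(key, []).append(ang(i, j, k))
    tors_vals: Dict[str, List[float]] = {}
    for i, j, k, l, key in terms["torsions"]:
        tors_vals.setdefault(key, []).append(tors(i, j, k, l))

    kb = _DEFAULT_STIFFNESS["bond_k"]
    ka = _DEFAULT_STIFFNESS["angle_k"]
    kt = _DEFAULT_STIFFNESS["torsion_k"]
    bonds = {key: BondParam(kb, float(np.mean(v))) for key, v in bond_vals.items()}
    angles = {key: AngleParam(ka, float(np.mean(v))) for key, v in angle_vals.items()}
    torsions = {key: TorsionParam(kt, 1, float(_circmean(v)))
                for key, v in tors_vals.items()}

    s1, s2 = fixtures.duplex_strands("GCGC")
    cg1, cg2 = map_to_cg(s1), map_to_cg(s2)
    n = 4
    r0 = float(np.mean([
        np.linalg.norm(cg1.coords[5 * k + 2] - cg2.coords[5 * (n - 1 - k) + 2])
        for k in range(n)
    ]))
    pairing = {cls: PairWell(eps, r0, 1.0)
               for cls, eps in _DEFAULT_PAIR_EPS.items()}
    # r_ev must sit below the attractive minima the model forms (paired
    # B1-B1 ~ 3.7 Å, bonded S-P ~ 4.0 Å, closure b0 = 3.8 Å), otherwise the
    # repulsive floor fights every native contact
    return ForceFieldParams(bonds, angles, torsions, pairing,
                            r_ev=3.5, eps_ev=1.0, pair_scale=1.0)


def _circmean(values: Sequence[float]) -> float:
    s = np.mean(np.sin(values))
    c = np.mean(np.cos(values))
    return math.atan2(s, c)


def params_to_dict(p: ForceFieldParams) -> dict:
    return {
        "version": 1,
        "bonds": {k: {"k": v.k, "b0": v.b0} for k, v in sorted(p.bonds.items())},
        "angles": {k: {"k": v.k, "theta0": v.theta0}
                   for k, v in sorted(p.angles.items())},
        "torsions": {k: {"k": v.k, "n": v.n, "phi0": v.phi0}
                     for k, v in sorted(p.torsions.items())},
        "pairing": {k: {"eps": v.eps, "r0": v.r0, "sigma": v.sigma}
                    for k, v in sorted(p.pairing.items())},
        "excluded_volume": {"r_ev": p.r_ev, "eps": p.eps_ev},
    }


def params_from_dict(d: dict) -> ForceFieldParams:
    return ForceFieldParams(
        bonds={k: BondParam(v["k"], v["b0"]) for k, v in d["bonds"].items()},
        angles={k: AngleParam(v["k"], v["theta0"]) for k, v in d["angles"].items()},
        torsions={k: TorsionParam(v["k"], int(v["n"]), v["phi0"])
                  for k, v in d["torsions"].items()},
        pairing={k: PairWell(v["eps"], v["r0"], v["sigma"])
                 for k, v in d["pairing"].items()},
        r_ev=d["excluded_volume"]["r_ev"],
        eps_ev=d["excluded_volume"]["eps"],
    )


_default_cache: Optional[ForceFieldParams] = None


def default_params() -> ForceFieldParams:
    """Load the versioned default parameter file shipped with the package."""
    global _default_cache
    if _default_cache is None:
        import importlib.resources as res

        import yaml

        text = (res.files("circfold") / "data" / "forcefield_v1.yaml").read_text()
        _default_cache = params_from_dict(yaml.safe_load(text))
    return _default_cache
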