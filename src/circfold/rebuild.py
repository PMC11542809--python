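"""Kabsch superposition and all-atom reconstruction from CG models.

Reconstruction uses single-nucleotide fragment matching: for every
nucleotide, each candidate all-atom fragment (idealized conformers with
precomputed five-bead CG images) is rigidly superposed onto the target's
five beads; the best-fitting fragment's atoms are placed with the winning
transform.  Backbone continuity between consecutive residues is then
handled by a limited steepest-descent geometry cleanup rather than during
fragment placement, which keeps the match step strictly single-nucleotide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import GeometryError
from .structure_io import AllAtomStructure, CGChain, Residue, map_to_cg

# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


@dataclass
class Superposition:
    rotation: np.ndarray     # 3x3, proper (det = +1)
    translation: np.ndarray  # 3-vector, Å
    rmsd: float              # Å

    def apply(self, y: np.ndarray) -> np.ndarray:
        return y @ self.rotation.T + self.translation


def kabsch_superpose(x: np.ndarray, y: np.ndarray,
                     weights: Optional[np.ndarray] = None) -> Superposition:
    """Least-squares optimal proper rotation + translation of ``y`` onto ``x``.

    Reflections are excluded; the returned rmsd is
    sqrt(sum w ||x - (R y + t)||^2 / sum w).  Requires at least 3
    non-collinear points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("point sets must both have shape (n, 3)")
    n = x.shape[0]
    if n < 3:
        raise GeometryError("need at least 3 points to superpose")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    cx = (w[:, None] * x).sum(axis=0) / wsum
    cy = (w[:, None] * y).sum(axis=0) / wsum
    xc = x - cx
    yc = y - cy
    # collinearity check on the target
    if np.linalg.matrix_rank(xc, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) point set")
    h = (w[:, None] * yc).T @ xc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cx - rot @ cy
    dev = xc - yc @ rot.T
    rmsd = math.sqrt(float((w * np.sum(dev * dev, axis=1)).sum() / wsum))
    return Superposition(rot, trans, rmsd)


# ---------------------------------------------------------------------------
# Fragment library
# ---------------------------------------------------------------------------

#: base-spin offsets (deg) about the sugar->WC-edge axis — the soft mode of
#: the five-bead geometry (the attachment angles are nearly collinear, so
#: the triangle spins almost freely against the soft torsion)
FRAGMENT_SPIN_VARIANTS = tuple(float(x) for x in range(-150, 151, 15))
#: phosphate-bend offsets (deg) of the P-S-B1 virtual angle
FRAGMENT_BEND_VARIANTS = (-25.0, 0.0, 25.0)


@dataclass
class Fragment:
    base: str
    atom_names: Tuple[str, ...]
    atom_coords: np.ndarray  # (n_atoms, 3)
    cg_image: np.ndarray     # (5, 3)


@dataclass
class FragmentLibrary:
    fragments: Dict[str, List[Fragment]]

    def for_base(self, base: str) -> List[Fragment]:
        if base not in self.fragments or not self.fragments[base]:
            raise KeyError(f"no fragment for base {base!r} in the library")
        return self.fragments[base]

    @property
    def size(self) -> int:
        return sum(len(v) for v in self.fragments.values())


def _rotate_about_axis(points: np.ndarray, origin: np.ndarray,
                       axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = axis
    p = points - origin
    cos, sin = math.cos(angle_rad), math.sin(angle_rad)
    rot = (p * cos + np.cross(k, p) * sin
           + np.outer(p @ k, k) * (1 - cos))
    return rot + origin


def build_fragment_library() -> FragmentLibrary:
    """Idealized single-nucleotide conformers with precomputed CG images.

    Each base contributes a grid of conformers spanning the two soft
    internal coordinates of the five-bead geometry: the base-triangle spin
    about the sugar->WC-edge axis and the phosphate bend of the P-S-B1
    virtual angle.  The CG image of every fragment is exactly ``map_to_cg``
    of its atoms.
    """
    from .fixtures import nucleotide_template
    from .structure_io import ATOMIC_MASSES, BASE_GROUPS

    phosphate = ("P", "OP1", "OP2", "O5'", "C5'")
    lib: Dict[str, List[Fragment]] = {}
    for base in "ACGU":
        names, local = nucleotide_template(base)
        c4 = local[names.index("C4'")]
        wc_group = BASE_GROUPS[base][0]
        w = np.array([ATOMIC_MASSES[a[0]] for a in wc_group])
        b1c = (w[:, None] * np.array(
            [local[names.index(a)] for a in wc_group])).sum(axis=0) / w.sum()
        spin_axis = b1c - c4
        bend_axis = np.cross(local[names.index("P")] - c4, spin_axis)
        base_atoms = set(a for grp in BASE_GROUPS[base] for a in grp)
        base_mask = np.array([n in base_atoms for n in names])
        phos_mask = np.array([n in phosphate for n in names])
        frags = []
        for spin in FRAGMENT_SPIN_VARIANTS:
            for bend in FRAGMENT_BEND_VARIANTS:
                coords = local.copy()
                coords[base_mask] = _rotate_about_axis(
                    coords[base_mask], c4, spin_axis, math.radians(spin))
                coords[phos_mask] = _rotate_about_axis(
                    coords[phos_mask], c4, bend_axis, math.radians(bend))
                res = Residue(1, base,
                              {n: coords[i] for i, n in enumerate(names)})
                cg = map_to_cg(AllAtomStructure([res]))
                frags.append(Fragment(base, names, coords, cg.coords.copy()))
        lib[base] = frags
    return FragmentLibrary(lib)


# ---------------------------------------------------------------------------
# Reconstruction
# ---------------------------------------------------------------------------

def rebuild_all_atom(chain: CGChain, lib: Optional[FragmentLibrary] = None,
                     return_rmsd: bool = False):
    """All-atom model from a CG chain by single-nucleotide fragment matching.

    Per nucleotide the candidate fragment whose CG image superposes onto the
    target beads with minimal RMSD wins, and its atoms are placed with that
    transform.  Residues are renumbered 1..N.
    """
    lib = lib or build_fragment_library()
    residues: List[Residue] = []
    match_rmsd = np.zeros(chain.n_nt)
    for i in range(chain.n_nt):
        base = chain.sequence[i]
        target = chain.coords[5 * i:5 * i + 5]
        best: Tuple[float, Fragment, Superposition] = None
        for frag in lib.for_base(base):
            sup = kabsch_superpose(target, frag.cg_image)
            if best is None or sup.rmsd < best[0]:
                best = (sup.rmsd, frag, sup)
        rmsd, frag, sup = best
        match_rmsd[i] = rmsd
        placed = sup.apply(frag.atom_coords)
        residues.append(Residue(i + 1, base,
                                {n: placed[k] for k, n in enumerate(frag.atom_names)}))
    structure = AllAtomStructure(residues)
    if return_rmsd:
        return structure, match_rmsd
    return structure


# ---------------------------------------------------------------------------
# Geometry cleanup
# ---------------------------------------------------------------------------

O3P_BOND = 1.6     # Å, target inter-residue O3'-P distance
CLASH_DIST = 2.5   # Å, heavy-atom clash threshold
MAX_MOTION = 2.0   # Å, cap on per-atom displacement


def geometry_cleanup(structure: AllAtomStructure, steps: int = 200,
                     circular: bool = False,
                     step_size: float = 0.02) -> AllAtomStructure:
    """Best-effort local repair of backbone gaps and steric clashes.

    Steepest descent on a quadratic objective: inter-residue O3'-P bond
    restraints (target 1.6 Å) plus a short-range heavy-atom clash repulsion
    below 2.5 Å (bonded O3'-P neighbors exempt).  No atom ever moves more
    than 2 Å from its starting position.
    """
    residues = structure.residues
    names: List[Tuple[int, str]] = []
    coords: List[np.ndarray] = []
    res_of: List[int] = []
    for ri, res in enumerate(residues):
        for n, p in res.atoms.items():
            names.append((ri, n))
            coords.append(p)
            res_of.append(ri)
    x0 = np.array(coords)
    x = x0.copy()
    res_of_arr = np.array(res_of)
    index = {key: i for i, key in enumerate(names)}

    bond_pairs = []
    exempt = set()
    n_res = len(residues)
    links = range(n_res) if circular else range(n_res - 1)
    # 1-2/1-3 neighborhood across the phosphodiester linkage is bonded
    # chemistry, not a clash
    for ri in links:
        rj = (ri + 1) % n_res
        a = index.get((ri, "O3'"))
        b = index.get((rj, "P"))
        if a is not None and b is not None:
            bond_pairs.append((a, b))
        for n1 in ("O3'", "C3'"):
            for n2 in ("P", "OP1", "OP2", "O5'"):
                i1, i2 = index.get((ri, n1)), index.get((rj, n2))
                if i1 is not None and i2 is not None:
                    exempt.add((i1, i2))
                    exempt.add((i2, i1))
    bond_pairs = np.array(bond_pairs, dtype=int).reshape(-1, 2)
    bonded = exempt

    n_atoms = len(x)
    for _ in range(steps):
        g = np.zeros_like(x)
        if len(bond_pairs):
            d = x[bond_pairs[:, 0]] - x[bond_pairs[:, 1]]
            r = np.linalg.norm(d, axis=1)
            coef = 2.0 * (r - O3P_BOND) / np.maximum(r, 1e-9)
            gb = coef[:, None] * d
            np.add.at(g, bond_pairs[:, 0], gb)
            np.add.at(g, bond_pairs[:, 1], -gb)
        # clash gradient: non-same-residue atom pairs below threshold
        diff = x[:, None, :] - x[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        same_res = res_of_arr[:, None] == res_of_arr[None, :]
        close = (dist < CLASH_DIST) & ~same_res
        np.fill_diagonal(close, False)
        for a, b in bonded:
            close[a, b] = close[b, a] = False
        ii, jj = np.nonzero(np.triu(close, k=1))
        if len(ii):
            d = x[ii] - x[jj]
            r = np.linalg.norm(d, axis=1)
            coef = -2.0 * (CLASH_DIST - r) / np.maximum(r, 1e-9)
            gc = coef[:, None] * d
            np.add.at(g, ii, gc)
            np.add.at(g, jj, -gc)
        if not np.any(g):
            break
        x_new = x - step_size * g
        # cap total displacement from the start
        disp = x_new - x0
        norms = np.linalg.norm(disp, axis=1)
        over = norms > MAX_MOTION
        if np.any(over):
            disp[over] *= (MAX_MOTION / norms[over])[:, None]
            x_new = x0 + disp
        x = x_new

    out: List[Residue] = []
    k = 0
    for ri, res in enumerate(residues):
        atoms = {}
        for n in res.atoms:
            atoms[n] = x[index[(ri, n)]]
        out.append(Residue(res.number, res.base, atoms))
    return AllAtomStructure(out, structure.chain_id)
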