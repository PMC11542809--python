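"""Deterministic toy-structure generators.

All fixtures are built from a single idealized nucleotide template per base
(heavy atoms from the Chemical Component Dictionary shipped with biotite,
with the backbone/sugar geometry unified across bases) threaded along
analytic curves: an idealized helix for duplexes, circular arcs for loops
and open strands.  The helical placement constants below were fitted once so
that a single rigid template repeated by helical symmetry yields a continuous
backbone (O3'-P ~ 1.6 Å, S-P ~ 4 Å), Watson-Crick bead distances of a few Å
and no steric overlap; because the template's internal conformation is the
idealized CCD one rather than a crystallographic A-form conformer, the
resulting helix is somewhat stretched relative to true A-form.  See
``scripts/fit_geometry.py`` for the fitting procedure.

Fixture kinds:

* ``ideal_helix``  — single-strand ideal helix; every bonded force-field
  term sits exactly at its equilibrium value.
* ``hairpin``      — stem-loop (configurable stem/loop lengths).
* ``dumbbell``     — two stems sharing a coaxial helix across the BSJ, a loop
  at each end; the canonical helix-circular toy.
* ``open_hairpin`` — hairpin secondary structure threaded on an open planar
  arc so the chain ends are far apart (end-closure test input).
* ``defect:<kind>``— chains with exactly one planted locally-irrational
  topology (template_free_loop, backbone_tangle, base_collision, sharp_twist).
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import ConfigError
from .structure_io import (
    AllAtomStructure,
    CGChain,
    Residue,
    map_to_cg,
)

# ---------------------------------------------------------------------------
# Helical placement constants (fitted once; see scripts/fit_geometry.py)
# ---------------------------------------------------------------------------

RISE = 5.373164925808755      # Å per nucleotide along the helix axis
TWIST = 0.46169484291667184   # helical twist per nucleotide, rad
R_BB = 6.633468768826814      # radius of the C4' trace, Å
#: extra rotation of the nucleotide template in its local frame (ZYX Euler, rad)
POSE_EULER = (-0.24162288827035372, -0.24917617305409334, -0.7050565230048285)
#: angular phase of the complementary strand relative to its partner
PHI2 = 1.6457115986238895
#: axial offset of the complementary strand, Å
Z2 = -0.34809763129422266
#: contour spacing used when threading residues along arcs, Å
ARC_SPACING = 6.2

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

_REFERENCE_BASE = "G"  # donor of the unified backbone/sugar geometry
_SUGAR_RING = ("C1'", "C2'", "C3'", "C4'", "O4'")
_BACKBONE_SUGAR = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'",
                   "O3'", "C2'", "O2'", "C1'")


def _euler_zyx(a: float, b: float, c: float) -> np.ndarray:
    ca, sa = math.cos(a), math.sin(a)
    cb, sb = math.cos(b), math.sin(b)
    cc, sc = math.cos(c), math.sin(c)
    rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rx = np.array([[1, 0, 0], [0, cc, -sc], [0, sc, cc]])
    return rz @ ry @ rx


@lru_cache(maxsize=None)
def _ccd_heavy(base: str) -> Dict[str, np.ndarray]:
    """Heavy atoms (ideal coordinates) of a ribonucleotide, OP3 dropped."""
    import biotite.structure.info as info

    arr = info.residue(base)
    out: Dict[str, np.ndarray] = {}
    for name, coord, elem in zip(arr.atom_name, arr.coord, arr.element):
        if elem == "H" or name == "OP3":
            continue
        out[str(name)] = np.array(coord, dtype=float)
    return out


def _kabsch_rt(x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Rotation/translation mapping point set y onto x (least squares)."""
    cx, cy = x.mean(axis=0), y.mean(axis=0)
    h = (y - cy).T @ (x - cx)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, cx - r @ cy


@lru_cache(maxsize=None)
def nucleotide_template(base: str) -> Tuple[Tuple[str, ...], np.ndarray]:
    """Heavy-atom template of a base in the canonical local pose.

    The backbone/sugar atoms are taken from one reference nucleotide so the
    backbone geometry is identical for all bases; the base atoms are grafted
    on by superposing the sugar ring.  Canonical pose: C4' at the origin,
    local x toward the base centroid, local z completing a right-handed frame
    with the C4'->P direction.
    """
    ref = _ccd_heavy(_REFERENCE_BASE)
    atoms: Dict[str, np.ndarray] = {n: ref[n].copy() for n in _BACKBONE_SUGAR}
    donor = _ccd_heavy(base)
    ring_ref = np.array([ref[n] for n in _SUGAR_RING])
    ring_don = np.array([donor[n] for n in _SUGAR_RING])
    rot, trans = _kabsch_rt(ring_ref, ring_don)
    for name, pos in donor.items():
        if name in _BACKBONE_SUGAR:
            continue
        atoms[name] = rot @ pos + trans

    # Canonical frame from backbone atoms only, so the local backbone
    # geometry is bit-identical across bases: local x toward C1' (and hence
    # the base), local y in the C4'->P half-plane.
    origin = atoms["C4'"]
    e1 = atoms["C1'"] - origin
    e1 /= np.linalg.norm(e1)
    w = atoms["P"] - origin
    e2 = w - (w @ e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    frame = np.stack([e1, e2, e3], axis=1)  # columns
    adjust = _euler_zyx(*POSE_EULER)
    names = tuple(sorted(atoms))
    local = np.array([(atoms[n] - origin) @ frame for n in names]) @ adjust.T
    return names, local


def _residue_from_template(base: str, origin: np.ndarray, rot: np.ndarray,
                           number: int) -> Residue:
    names, local = nucleotide_template(base)
    atoms = {n: origin + rot @ local[i] for i, n in enumerate(names)}
    return Residue(number, base, atoms)


@lru_cache(maxsize=None)
def cg_template(base: str) -> Tuple[np.ndarray, np.ndarray]:
    """CG bead local coordinates (5, 3) and masses (5,) of one template."""
    res = _residue_from_template(base, np.zeros(3), np.eye(3), 1)
    chain = map_to_cg(AllAtomStructure([res]))
    return chain.coords.copy(), chain.masses.copy()


# ---------------------------------------------------------------------------
# Frames along helices and arcs
# ---------------------------------------------------------------------------

def _frame(origin: np.ndarray, e1: np.ndarray, e3_hint: np.ndarray
           ) -> Tuple[np.ndarray, np.ndarray]:
    """Right-handed frame with local x = e1, local z ~ e3_hint."""
    e1 = e1 / np.linalg.norm(e1)
    e3 = e3_hint - (e3_hint @ e1) * e1
    e3 = e3 / np.linalg.norm(e3)
    e2 = np.cross(e3, e1)
    return origin, np.stack([e1, e2, e3], axis=1)


def helix_frame(k: int, strand: int = 1, phase: float = 0.0, z0: float = 0.0
                ) -> Tuple[np.ndarray, np.ndarray]:
    """Placement frame of base-pair step ``k`` on strand 1 or 2.

    Strand 1 runs 5'->3' along +z; strand 2 is the antiparallel complement,
    rotated by ``PHI2`` about the axis and running along -z.
    """
    if strand == 1:
        theta = k * TWIST + phase
        axis = np.array([0.0, 0.0, 1.0])
    else:
        theta = k * TWIST + phase + PHI2
        axis = np.array([0.0, 0.0, -1.0])
    radial = np.array([math.cos(theta), math.sin(theta), 0.0])
    origin = R_BB * radial + np.array([0.0, 0.0, k * RISE + z0 + (Z2 if strand == 2 else 0.0)])
    return _frame(origin, -radial, axis)


@lru_cache(maxsize=None)
def _helix_relative_rotation() -> np.ndarray:
    """Template rotation relative to the local backbone path frame.

    Measured once from the interior of a single-strand helix; reusing it
    when threading residues along arbitrary curves reproduces the helix's
    local backbone geometry (P on the 5' side, sensible virtual angles)
    wherever the curve is gently bent.
    """
    frames = [helix_frame(i, strand=1) for i in range(5)]
    s_pts = np.array([f[0] for f in frames])
    i = 2
    theta = i * TWIST
    hint = -np.array([math.cos(theta), math.sin(theta), 0.0])  # base direction
    t = s_pts[i + 1] - s_pts[i - 1]
    pf = _path_frame(t, hint)
    return pf.T @ frames[i][1]


def _path_frame(tangent: np.ndarray, normal_hint: np.ndarray) -> np.ndarray:
    t = tangent / np.linalg.norm(tangent)
    nv = normal_hint - (normal_hint @ t) * t
    nv = nv / np.linalg.norm(nv)
    b = np.cross(t, nv)
    return np.stack([nv, b, t], axis=1)


def frames_along_path(s_points: np.ndarray,
                      normal_hints: np.ndarray
                      ) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Residue frames for C4' positions threaded along an arbitrary path.

    The template keeps the helix-calibrated orientation relative to the
    local path frame (tangent from central differences, normal from the
    per-residue hint), so backbone continuity survives bends.
    """
    rel = _helix_relative_rotation()
    n = len(s_points)
    frames = []
    for i in range(n):
        t = s_points[min(i + 1, n - 1)] - s_points[max(i - 1, 0)]
        pf = _path_frame(t, normal_hints[i])
        frames.append((s_points[i], pf @ rel))
    return frames


def cg_chain_along_path(sequence: str, s_points: np.ndarray,
                        normal_hints: Optional[np.ndarray] = None) -> CGChain:
    """CG chain with S beads on ``s_points`` and template-consistent P/base
    bead placement (see :func:`frames_along_path`)."""
    n = len(sequence)
    if normal_hints is None:
        normal_hints = _default_hints(s_points)
    frames = frames_along_path(np.asarray(s_points, dtype=float),
                               np.asarray(normal_hints, dtype=float))
    coords = np.zeros((5 * n, 3))
    masses = np.zeros(5 * n)
    for i, b in enumerate(sequence):
        local, m = cg_template(b)
        origin, rot = frames[i]
        coords[5 * i:5 * i + 5] = origin + (local - local[1]) @ rot.T
        masses[5 * i:5 * i + 5] = m
    return CGChain(sequence, coords, masses)


def _default_hints(s_points: np.ndarray) -> np.ndarray:
    n = len(s_points)
    hints = np.zeros((n, 3))
    for i in range(n):
        t = s_points[min(i + 1, n - 1)] - s_points[max(i - 1, 0)]
        t = t / np.linalg.norm(t)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(t @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        h = np.cross(t, ref)
        hints[i] = h / np.linalg.norm(h)
    return hints


def arc_frames(n: int, start: np.ndarray, end: np.ndarray, lift: np.ndarray,
               spacing: float = ARC_SPACING) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Frames for ``n`` residues along a circular arc from start to end.

    The arc bulges in the ``lift`` direction; its length is (n+1) * spacing
    (clamped so a circle through the end points exists).  Bases point away
    from the arc center, the local chain axis follows the tangent.
    """
    mid = 0.5 * (start + end)
    u = end - start
    c = 0.5 * np.linalg.norm(u)
    u = u / (2 * c)
    w = lift - (lift @ u) * u
    w = w / np.linalg.norm(w)
    target = max((n + 1) * spacing, 2.0 * c + 1e-6)

    def arclen(s: float) -> float:
        r = math.hypot(s, c)
        alpha = math.atan2(c, s)
        return 2 * alpha * r

    lo, hi = -50.0, 500.0
    while arclen(hi) > target:
        hi *= 2
        if hi > 1e6:
            break
    # arclen is decreasing in s
    for _ in range(200):
        s = 0.5 * (lo + hi)
        if arclen(s) > target:
            lo = s
        else:
            hi = s
    s = 0.5 * (lo + hi)
    r = math.hypot(s, c)
    center = mid - s * w
    phi_a = math.atan2(s, -c)
    phi_b = math.atan2(s, c)
    if s < 0:
        # arc longer than a semicircle: go the long way, over the apex
        phi_b -= 2 * math.pi
    origins = []
    hints = []
    for m in range(1, n + 1):
        phi = phi_a + (phi_b - phi_a) * m / (n + 1)
        radial = math.cos(phi) * u + math.sin(phi) * w
        origins.append(center + r * radial)
        hints.append(radial)
    return frames_along_path(np.array(origins), np.array(hints))


def assemble(sequence: str, frames: List[Tuple[np.ndarray, np.ndarray]],
             start_number: int = 1) -> AllAtomStructure:
    if len(sequence) != len(frames):
        raise ValueError("sequence/frames length mismatch")
    residues = [
        _residue_from_template(b, origin, rot, start_number + i)
        for i, (b, (origin, rot)) in enumerate(zip(sequence, frames))
    ]
    return AllAtomStructure(residues)


# ---------------------------------------------------------------------------
# Named fixtures
# ---------------------------------------------------------------------------

def build_single_helix(sequence: str) -> AllAtomStructure:
    """Single-strand ideal helix; the bonded-parameter reference state."""
    frames = [helix_frame(i, strand=1) for i in range(len(sequence))]
    return assemble(sequence, frames)


def duplex_strands(sequence: str) -> Tuple[AllAtomStructure, AllAtomStructure]:
    """A duplex as two separate strands (used to calibrate pairing geometry).

    Strand 2 is the reverse complement, placed antiparallel so that base pair
    ``k`` couples strand-1 residue k with strand-2 residue n-1-k.
    """
    n = len(sequence)
    comp = "".join(COMPLEMENT[b] for b in sequence)
    frames1 = [helix_frame(k, strand=1) for k in range(n)]
    s2_seq = comp[::-1]
    frames2 = [helix_frame(n - 1 - m, strand=2) for m in range(n)]
    return assemble(sequence, frames1), assemble(s2_seq, frames2)


def _stem_sequences(n_stem: int) -> Tuple[str, str]:
    """Alternating G/C stem and its pairing partner read 5'->3'."""
    s1 = "".join("GC"[i % 2] for i in range(n_stem))
    s2 = "".join(COMPLEMENT[b] for b in s1)[::-1]
    return s1, s2


def build_hairpin(n_stem: int = 4, n_loop: int = 4,
                  loop_base: str = "A") -> Tuple[str, str, AllAtomStructure]:
    """Stem-loop: returns (sequence, dot-bracket, structure)."""
    if n_loop < 3:
        raise ConfigError("hairpin loops need at least 3 nt")
    s1, s2 = _stem_sequences(n_stem)
    seq = s1 + loop_base * n_loop + s2
    db = "(" * n_stem + "." * n_loop + ")" * n_stem
    frames = [helix_frame(k, strand=1) for k in range(n_stem)]
    top1 = helix_frame(n_stem, strand=1)[0]
    top2 = helix_frame(n_stem, strand=2)[0]
    lift = np.array([0.0, 0.0, 1.0])
    frames += arc_frames(n_loop, top1, top2, lift)
    frames += [helix_frame(n_stem - 1 - m, strand=2) for m in range(n_stem)]
    return seq, db, assemble(seq, frames)


def build_dumbbell(n_stem: int = 4, n_loop: int = 4) -> Tuple[str, str, AllAtomStructure]:
    """Two coaxially stacked stems with terminal loops; helix-circular BSJ.

    The chain is threaded so that the backbone edge (N, 1) sits in the middle
    of a continuous 2*n_stem helix, which is what makes the BSJ helix-type
    once the chain is circularized.
    """
    n_total_bp = 2 * n_stem
    strand1_full, strand2_full = _stem_sequences(n_total_bp)
    # helix positions: strand-1 residues occupy bp steps 0..2s-1 bottom->top;
    # chain order: [s..2s-1] (nts 1..s), top loop, strand2 top->bottom
    # (nts s+nl+1 .. s+nl+2s), bottom loop, [0..s-1] (last s nts).
    s, nl = n_stem, n_loop
    seq = (strand1_full[s:] + "A" * nl + strand2_full + "A" * nl + strand1_full[:s])
    db = ("(" * s + "." * nl + ")" * s + "(" * s + "." * nl + ")" * s)
    frames: List[Tuple[np.ndarray, np.ndarray]] = []
    frames += [helix_frame(k, strand=1) for k in range(s, 2 * s)]
    top1 = helix_frame(2 * s, strand=1)[0]
    top2 = helix_frame(2 * s, strand=2)[0]
    frames += arc_frames(nl, top1, top2, np.array([0.0, 0.0, 1.0]))
    frames += [helix_frame(2 * s - 1 - m, strand=2) for m in range(2 * s)]
    bot2 = helix_frame(-1, strand=2)[0]
    bot1 = helix_frame(-1, strand=1)[0]
    frames += arc_frames(nl, bot2, bot1, np.array([0.0, 0.0, -1.0]))
    frames += [helix_frame(k, strand=1) for k in range(s)]
    return seq, db, assemble(seq, frames)


def build_open_hairpin(n_nt: int = 24, end_separation: float = 30.0
                       ) -> Tuple[str, str, AllAtomStructure]:
    """Hairpin 2D structure threaded on an open planar arc.

    The 3D conformation is a near-circle whose free ends are
    ``end_separation`` Å apart, emulating a linear initial model whose
    termini must be pulled together by the end-closure stage.
    """
    n_stem = n_nt // 3
    n_loop = n_nt - 2 * n_stem
    s1, s2 = _stem_sequences(n_stem)
    seq = s1 + "A" * n_loop + s2
    db = "(" * n_stem + "." * n_loop + ")" * n_stem

    def gap_angle(radius: float) -> float:
        dphi = 2 * math.asin(min(1.0, ARC_SPACING / (2 * radius)))
        return (n_nt - 1) * dphi + 2 * math.asin(min(1.0, end_separation / (2 * radius)))

    lo = max(ARC_SPACING, end_separation) / 2 + 1e-6
    hi = 1e4
    for _ in range(200):
        r = 0.5 * (lo + hi)
        if gap_angle(r) > 2 * math.pi:
            lo = r
        else:
            hi = r
    r = 0.5 * (lo + hi)
    dphi = 2 * math.asin(ARC_SPACING / (2 * r))
    origins = []
    hints = []
    for i in range(n_nt):
        phi = i * dphi
        radial = np.array([math.cos(phi), math.sin(phi), 0.0])
        origins.append(r * radial)
        hints.append(radial)
    frames = frames_along_path(np.array(origins), np.array(hints))
    return seq, db, assemble(seq, frames)


# ---------------------------------------------------------------------------
# Planted-defect fixtures (CG-level constructions)
# ---------------------------------------------------------------------------

def _jitter_perp(points: np.ndarray, rng: np.random.Generator,
                 amplitude: float, keep: Tuple[int, ...] = ()) -> np.ndarray:
    """Deterministic small perpendicular displacements (breaks repetition)."""
    n = len(points)
    out = points.copy()
    for i in range(n):
        if i in keep:
            continue
        t = points[min(i + 1, n - 1)] - points[max(i - 1, 0)]
        t = t / np.linalg.norm(t)
        v = rng.normal(size=3)
        v -= (v @ t) * t
        nv = np.linalg.norm(v)
        if nv > 1e-9:
            out[i] = out[i] + amplitude * v / nv
    return out


def build_defect_sharp_twist(n_nt: int = 20, angle_deg: float = 25.0
                             ) -> Tuple[str, str, CGChain]:
    """Open chain with one acutely kinked backbone apex.

    Two straight legs meet at an interior path angle of ``angle_deg``; gentle
    perpendicular jitter elsewhere keeps the rest of the chain irregular.
    """
    rng = np.random.default_rng(20240301)
    seq = "".join("ACGU"[i % 4] for i in range(n_nt))
    half = n_nt // 2
    spacing = 6.0
    d1 = np.array([1.0, 0.0, 0.0])
    ang = math.radians(angle_deg)
    d2 = np.array([-math.cos(ang), math.sin(ang), 0.12])
    d2 /= np.linalg.norm(d2)
    apex = np.zeros(3)
    pts = [apex - (half - 1 - i) * spacing * d1 for i in range(half)]
    pts += [apex + (k + 1) * spacing * d2 for k in range(n_nt - half)]
    s_pts = _jitter_perp(np.array(pts), rng, 0.7,
                         keep=(half - 2, half - 1, half))
    hints = np.tile(np.array([0.0, 0.0, 1.0]), (n_nt, 1))
    chain = cg_chain_along_path(seq, s_pts, hints)
    return seq, "." * n_nt, chain


def build_defect_template_free_loop(n_stem: int = 4, n_loop: int = 18
                                    ) -> Tuple[str, str, AllAtomStructure]:
    """Hairpin whose long loop repeats one internal-coordinate motif.

    Every loop nucleotide is placed by the same helical step, so consecutive
    local descriptors (virtual bond lengths and torsions) are identical --
    the signature of a template-free loop.
    """
    s1, s2 = _stem_sequences(n_stem)
    seq = s1 + "A" * n_loop + s2
    db = "(" * n_stem + "." * n_loop + ")" * n_stem
    frames = [helix_frame(k, strand=1) for k in range(n_stem)]
    # repetitive loop: wide, gentle helix with constant twist/rise
    top1 = helix_frame(n_stem, strand=1)
    base_origin = top1[0]
    r_loop, twist_loop, rise_loop = 14.0, 2 * math.pi / (n_loop + 2), 1.0
    center = base_origin + np.array([r_loop, 0.0, 3.0])
    origins = []
    hints = []
    for m in range(n_loop):
        phi = math.pi + (m + 1) * twist_loop
        radial = np.array([math.cos(phi), math.sin(phi), 0.0])
        origins.append(center + r_loop * radial
                       + np.array([0.0, 0.0, m * rise_loop]))
        hints.append(radial)
    frames += frames_along_path(np.array(origins), np.array(hints))
    frames += [helix_frame(n_stem - 1 - m, strand=2) for m in range(n_stem)]
    return seq, db, assemble(seq, frames)


def _place_explicit(seq: str, coords: np.ndarray, masses: np.ndarray, i: int,
                    p_pos: np.ndarray, s_pos: np.ndarray,
                    hint: np.ndarray, tangent: np.ndarray) -> None:
    """Place one nucleotide with explicit P and S bead positions."""
    local, m = cg_template(seq[i])
    _, rot = _frame(s_pos, hint, tangent)
    block = s_pos + (local - local[1]) @ rot.T
    block[0] = p_pos
    block[1] = s_pos
    coords[5 * i:5 * i + 5] = block
    masses[5 * i:5 * i + 5] = m


def build_defect_base_collision(n_nt: int = 12) -> Tuple[str, str, CGChain]:
    """Chain whose backbone threads the slab between two stacked bases.

    Nucleotides 1-2 are stacked 3.4 Å apart; the S(8)-P(9) backbone bond
    runs along the common base-plane normal through the slab midpoint,
    crossing both planes inside the triangle footprints; the rest of the
    chain detours around the slab.
    """
    seq = "".join("GACU"[i % 4] for i in range(n_nt))
    coords = np.zeros((5 * n_nt, 3))
    masses = np.zeros(5 * n_nt)

    # stacked pair (consistent tangents -> parallel base planes)
    stack_pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 3.4]])
    stack_hints = np.array([[-1.0, 0.0, 0.0]] * 2)
    stack = cg_chain_along_path(seq[:2], stack_pts, stack_hints)
    coords[:10] = stack.coords
    masses[:10] = stack.masses
    cents = []
    for nt in (1, 2):
        b = [stack.coords[CGChain.bead_index(nt, k)] for k in ("B1", "B2", "B3")]
        cents.append(np.mean(b, axis=0))
    mid = 0.5 * (cents[0] + cents[1])
    normal = np.cross(
        stack.coords[CGChain.bead_index(1, "B2")] - stack.coords[CGChain.bead_index(1, "B1")],
        stack.coords[CGChain.bead_index(1, "B3")] - stack.coords[CGChain.bead_index(1, "B1")])
    normal /= np.linalg.norm(normal)
    if normal @ (cents[1] - cents[0]) < 0:
        normal = -normal

    # lateral direction away from both the slab and the stack backbone
    lateral = mid - np.array([0.0, 0.0, mid[2]])
    lateral /= np.linalg.norm(lateral)

    # thread nts 8-9: S8 and P9 straddle the slab along the normal
    s8 = mid - 1.9 * normal
    p9 = mid + 1.9 * normal
    p8 = mid - 5.7 * normal
    s9 = mid + 5.7 * normal
    _place_explicit(seq, coords, masses, 7, p8, s8, lateral, normal)
    _place_explicit(seq, coords, masses, 8, p9, s9, lateral, normal)

    # connector nts 3-7 detours behind the stack backbone (x >= 0 side)
    entry = p8 - 2.0 * normal + 6.0 * lateral
    conn_pts = np.array([
        [8.0, -4.0, 9.0],
        [12.0, -9.0, 7.0],
        [9.0, -14.0, 3.0],
        [3.0, -15.0, 0.0],
        entry,
    ])
    conn = cg_chain_along_path(seq[2:7], conn_pts)
    coords[10:35] = conn.coords
    masses[10:35] = conn.masses

    # exit nts 10-12
    exit_pts = np.array([
        s9 + 4.0 * normal + 2.0 * lateral,
        s9 + 8.0 * normal + 6.0 * lateral,
        s9 + 11.0 * normal + 11.0 * lateral,
    ])
    tail = cg_chain_along_path(seq[9:], exit_pts)
    coords[45:] = tail.coords
    masses[45:] = tail.masses
    return seq, "." * n_nt, CGChain(seq, coords, masses)


def build_defect_backbone_tangle(n_nt: int = 16) -> Tuple[str, str, CGChain]:
    """Chain with two distant backbone windows wound through each other.

    The backbone beads of nucleotides 6-7 trace three quarters of a ring in
    the xz-plane; the backbone of nucleotides 12-13 runs straight through
    its center along y (a Hopf-link-like interlock once both open windows
    are virtually closed).
    """
    rng = np.random.default_rng(20240303)
    seq = "".join("CUGA"[i % 4] for i in range(n_nt))
    coords = np.zeros((5 * n_nt, 3))
    masses = np.zeros(5 * n_nt)

    ring_r = 2.83
    ring = {a: ring_r * np.array([math.cos(math.radians(a)), 0.0,
                                  math.sin(math.radians(a))])
            for a in (225.0, 135.0, 45.0, -45.0)}
    # explicit windows -------------------------------------------------
    _place_explicit(seq, coords, masses, 5, ring[225.0], ring[135.0],
                    np.array([-1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]))
    _place_explicit(seq, coords, masses, 6, ring[45.0], ring[-45.0],
                    np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, -1.0]))
    axis = {y: np.array([0.0, y, 0.0]) for y in (-6.0, -2.0, 2.0, 6.0)}
    _place_explicit(seq, coords, masses, 11, axis[-6.0], axis[-2.0],
                    np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
    _place_explicit(seq, coords, masses, 12, axis[2.0], axis[6.0],
                    np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))

    # connectors (path-threaded, gently jittered) ----------------------
    lead_end = ring[225.0] + np.array([-5.0, -2.0, -3.0])
    d_in = (lead_end - np.array([-30.0, -14.0, -18.0])) / 5.0
    lead = np.array([np.array([-30.0, -14.0, -18.0]) + k * d_in
                     for k in range(5)])
    lead[-1] = lead_end
    lead = _jitter_perp(lead, rng, 0.6, keep=(4,))
    sub = cg_chain_along_path(seq[:5], lead)
    coords[:25] = sub.coords
    masses[:25] = sub.masses

    mid = np.array([
        [6.0, -2.0, -6.0],
        [8.0, -7.0, -8.0],
        [6.0, -12.0, -6.0],
        [3.0, -10.0, -3.0],
    ])
    mid = _jitter_perp(mid, rng, 0.5, keep=(0, 3))
    sub = cg_chain_along_path(seq[7:11], mid)
    coords[35:55] = sub.coords
    masses[35:55] = sub.masses

    tail = np.array([
        [2.0, 10.0, 3.0],
        [4.0, 14.0, 6.0],
        [6.0, 18.0, 9.0],
    ])
    tail = _jitter_perp(tail, rng, 0.6, keep=(0,))
    sub = cg_chain_along_path(seq[13:], tail)
    coords[65:] = sub.coords
    masses[65:] = sub.masses
    return seq, "." * n_nt, CGChain(seq, coords, masses)


# ---------------------------------------------------------------------------
# Dispatcher
# ---------------------------------------------------------------------------

FIXTURE_KINDS = (
    "ideal_helix", "hairpin", "dumbbell", "open_hairpin",
    "defect:sharp_twist", "defect:template_free_loop",
    "defect:base_collision", "defect:backbone_tangle",
)


def generate_fixture(kind: str, **params):
    """Return (sequence, dot-bracket, structure) for a named fixture kind.

    The structure is an :class:`AllAtomStructure` for helical fixtures and a
    :class:`CGChain` for the bead-level planted-defect constructions.
    """
    if kind == "ideal_helix":
        n = params.pop("n_nt", 12)
        seq = params.pop("sequence", "".join("GCAU"[i % 4] for i in range(n)))
        if params:
            raise ConfigError(f"unknown fixture parameters {sorted(params)}")
        return seq, "." * len(seq), build_single_helix(seq)
    if kind == "hairpin":
        return build_hairpin(**params)
    if kind == "dumbbell":
        return build_dumbbell(**params)
    if kind == "open_hairpin":
        return build_open_hairpin(**params)
    if kind == "defect:sharp_twist":
        return build_defect_sharp_twist(**params)
    if kind == "defect:template_free_loop":
        return build_defect_template_free_loop(**params)
    if kind == "defect:base_collision":
        return build_defect_base_collision(**params)
    if kind == "defect:backbone_tangle":
        return build_defect_backbone_tangle(**params)
    raise ConfigError(f"unknown fixture kind {kind!r}; known: {FIXTURE_KINDS}")
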