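"""Detectors for the four classes of locally irrational topology.

Circular-RNA models assembled from template fragments frequently contain
physically implausible local geometry.  Four recurring classes are audited
here, all on the coarse-grained bead representation:

* **template-free loop** — a long loop (>= 15 nt) whose nucleotides all show
  nearly the same local pose (identical virtual bond lengths and torsions),
  the signature of a single-strand placed with one repeated template motif;
* **backbone tangle** — two short backbone windows wound through each other
  ("sticky knot"), detected via the discrete Gauss linking number of the
  virtually closed window polylines;
* **base collision** — a backbone segment threading the slab between two
  sequence-adjacent bases and clashing with them;
* **sharp twist** — an abnormally acute virtual angle along the backbone.

Thresholds are configuration-exposed; the defaults were calibrated so the
ideal-helix fixture is clean while each planted-defect fixture fires exactly
its own detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .secondary_structure import PairTable
from .structure_io import CGChain

DEFECT_KINDS = ("template_free_loop", "backbone_tangle", "base_collision",
                "sharp_twist")


@dataclass
class Finding:
    kind: str
    residues: Tuple[int, ...]  # 1-based nucleotide indices involved
    severity: float
    note: str = ""


@dataclass
class TopologyReport:
    findings: List[Finding]

    @property
    def counts_by_kind(self) -> Dict[str, int]:
        counts = {k: 0 for k in DEFECT_KINDS}
        for f in self.findings:
            counts[f.kind] += 1
        return counts

    @property
    def total(self) -> int:
        return len(self.findings)

    def summary_tsv(self) -> str:
        lines = ["kind\tcount"]
        for k, v in self.counts_by_kind.items():
            lines.append(f"{k}\t{v}")
        return "\n".join(lines) + "\n"

    def findings_tsv(self) -> str:
        lines = ["kind\tresidues\tseverity\tnote"]
        for f in self.findings:
            res = ",".join(map(str, f.residues))
            lines.append(f"{f.kind}\t{res}\t{f.severity:.4f}\t{f.note}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Backbone helpers
# ---------------------------------------------------------------------------

def _backbone(chain: CGChain) -> Tuple[np.ndarray, List[Tuple[int, str]]]:
    """Backbone bead coordinates in chain order [P1, S1, P2, S2, ...]."""
    coords = []
    labels = []
    for i in range(chain.n_nt):
        coords.append(chain.coords[5 * i])
        labels.append((i + 1, "P"))
        coords.append(chain.coords[5 * i + 1])
        labels.append((i + 1, "S"))
    return np.array(coords), labels


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cos = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cos))))


def _torsion(p: np.ndarray) -> float:
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.degrees(math.atan2(float(m1 @ n2), float(n1 @ n2)))


def _unpaired_runs(pt: PairTable) -> List[List[int]]:
    """Maximal runs of unpaired nucleotides (merged across the BSJ when
    circular)."""
    paired = set()
    for i, j in pt.pairs:
        paired.add(i)
        paired.add(j)
    unpaired = [i for i in range(1, pt.length + 1) if i not in paired]
    if not unpaired:
        return []
    runs: List[List[int]] = [[unpaired[0]]]
    for i in unpaired[1:]:
        if i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    if (pt.circular and len(runs) > 1 and runs[0][0] == 1
            and runs[-1][-1] == pt.length):
        runs[0] = runs.pop() + runs[0]
    return runs


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------

def detect_sharp_twists(chain: CGChain, angle_min: float = 60.0
                        ) -> List[Finding]:
    """Backbone virtual angles below ``angle_min`` degrees.

    Consecutive sub-threshold angles are merged into one finding; severity is
    the largest deficit (angle_min - angle) in the region.
    """
    bb, labels = _backbone(chain)
    n = len(bb)
    hits: List[Tuple[int, float]] = []
    rng_end = n if chain.circular else n - 2
    for k in range(rng_end):
        a, b, c = bb[k % n], bb[(k + 1) % n], bb[(k + 2) % n]
        ang = _angle(a, b, c)
        if ang < angle_min:
            hits.append((k + 1, angle_min - ang))  # index of the apex bead
    findings: List[Finding] = []
    if not hits:
        return findings
    group = [hits[0]]
    for h in hits[1:]:
        if h[0] - group[-1][0] <= 1:
            group.append(h)
        else:
            findings.append(_twist_finding(group, labels, n))
            group = [h]
    findings.append(_twist_finding(group, labels, n))
    return findings


def _twist_finding(group, labels, n) -> Finding:
    residues = sorted({labels[k % n][0] for k, _ in group})
    severity = max(s for _, s in group)
    return Finding("sharp_twist", tuple(residues), severity,
                   f"virtual backbone angle {severity:.1f} deg below threshold")


def detect_template_free_loops(chain: CGChain, pt: PairTable,
                               min_len: int = 15, dist_tol: float = 0.2,
                               torsion_tol: float = 5.0) -> List[Finding]:
    """Long unpaired runs whose nucleotides repeat one local pose.

    Per-nucleotide descriptors: the virtual bond lengths |P-S| and |S-P'|
    and the virtual torsion P-S-P'-S' (primes = next nucleotide).  A run is
    flagged when >= ``min_len`` consecutive descriptors agree pairwise within
    the tolerances.
    """
    n = chain.n_nt
    findings: List[Finding] = []
    for run in _unpaired_runs(pt):
        if len(run) < min_len:
            continue
        desc = []
        usable = []
        for nt in run:
            nxt = nt % n + 1
            if not chain.circular and nt == n:
                continue
            if nxt not in run and nxt != run[0]:
                # descriptor needs the successor; last run member may lack one
                if nxt - 1 != nt and not chain.circular:
                    continue
            P = chain.coords[CGChain.bead_index(nt, "P")]
            S = chain.coords[CGChain.bead_index(nt, "S")]
            Pn = chain.coords[CGChain.bead_index(nxt, "P")]
            Sn = chain.coords[CGChain.bead_index(nxt, "S")]
            d1 = float(np.linalg.norm(S - P))
            d2 = float(np.linalg.norm(Pn - S))
            tau = _torsion(np.array([P, S, Pn, Sn]))
            desc.append((d1, d2, tau))
            usable.append(nt)
        # longest window of pairwise-similar descriptors
        best: Tuple[int, int] = (0, 0)  # (length, start)
        start = 0
        for end in range(len(desc)):
            while start < end and not _window_similar(desc, start, end,
                                                      dist_tol, torsion_tol):
                start += 1
            if end - start + 1 > best[0]:
                best = (end - start + 1, start)
        if best[0] >= min_len:
            window = usable[best[1]:best[1] + best[0]]
            findings.append(Finding(
                "template_free_loop", tuple(window), float(best[0]),
                f"{best[0]} consecutive nt share one local pose"))
    return findings


def _window_similar(desc, start, end, dist_tol, torsion_tol) -> bool:
    for k in range(start, end):
        d1a, d2a, ta = desc[k]
        d1b, d2b, tb = desc[end]
        if abs(d1a - d1b) > dist_tol or abs(d2a - d2b) > dist_tol:
            return False
        dt = abs(ta - tb) % 360.0
        if min(dt, 360.0 - dt) > torsion_tol:
            return False
    return True


def detect_base_collisions(chain: CGChain, clash: float = 3.0,
                           footprint_margin: float = 1.0) -> List[Finding]:
    """Backbone segments threading between two sequence-adjacent bases.

    For each adjacent nucleotide pair (i, i+1) the base-bead triangles
    define two planes; a backbone bond (P-S or S-P) from nucleotides outside
    {i-1, i, i+1, i+2} is flagged when it crosses both planes inside the
    triangle footprints and approaches either base centroid within
    ``clash`` Å.  Findings are merged per base slab.
    """
    n = chain.n_nt
    findings: List[Finding] = []
    bb, labels = _backbone(chain)
    n_bb = len(bb)
    segs = []  # (nt_a, nt_b, p0, p1)
    seg_count = n_bb if chain.circular else n_bb - 1
    for k in range(seg_count):
        a, b = k % n_bb, (k + 1) % n_bb
        segs.append((labels[a][0], labels[b][0], bb[a], bb[b]))

    pairs = range(n) if chain.circular else range(n - 1)
    for i0 in pairs:
        i = i0 + 1
        j = i % n + 1
        tri = []
        ok = True
        for nt in (i, j):
            b1 = chain.coords[CGChain.bead_index(nt, "B1")]
            b2 = chain.coords[CGChain.bead_index(nt, "B2")]
            b3 = chain.coords[CGChain.bead_index(nt, "B3")]
            normal = np.cross(b2 - b1, b3 - b1)
            norm = np.linalg.norm(normal)
            if norm < 1e-8:
                ok = False
                break
            centroid = (b1 + b2 + b3) / 3.0
            radius = max(np.linalg.norm(p - centroid) for p in (b1, b2, b3))
            tri.append((centroid, normal / norm, radius + footprint_margin))
        if not ok:
            continue
        excluded = {(i - 2) % n + 1, i, j, j % n + 1}
        offenders = []
        worst = 0.0
        for nt_a, nt_b, p0, p1 in segs:
            if nt_a in excluded or nt_b in excluded:
                continue
            inside = True
            for centroid, normal, radius in tri:
                sa = float((p0 - centroid) @ normal)
                sb = float((p1 - centroid) @ normal)
                if sa * sb >= 0:
                    inside = False
                    break
                t = sa / (sa - sb)
                hit = p0 + t * (p1 - p0)
                if np.linalg.norm(hit - centroid) > radius:
                    inside = False
                    break
            if not inside:
                continue
            dmin = min(_point_segment_distance(c, p0, p1)
                       for c, _, _ in tri)
            if dmin < clash:
                offenders.append(nt_a)
                worst = max(worst, clash - dmin)
        if offenders:
            findings.append(Finding(
                "base_collision",
                tuple(sorted({i, j, *offenders})), worst,
                f"backbone passes between bases {i} and {j}"))
    return findings


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray
                            ) -> float:
    d = b - a
    t = float(np.clip((p - a) @ d / (d @ d), 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * d)))


def gauss_linking_number(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Discrete Gauss linking number of two closed polygonal curves.

    Uses the exact segment-pair solid-angle formula; curves are arrays of
    vertices, implicitly closed (last vertex connects back to the first).
    """
    total = 0.0
    na, nb = len(curve_a), len(curve_b)
    for ia in range(na):
        p1 = curve_a[ia]
        p2 = curve_a[(ia + 1) % na]
        for ib in range(nb):
            p3 = curve_b[ib]
            p4 = curve_b[(ib + 1) % nb]
            total += _segment_pair_linking(p1, p2, p3, p4)
    return total


def _segment_pair_linking(p1, p2, p3, p4) -> float:
    r13, r14 = p3 - p1, p4 - p1
    r23, r24 = p3 - p2, p4 - p2
    n1 = np.cross(r13, r14)
    n2 = np.cross(r14, r24)
    n3 = np.cross(r24, r23)
    n4 = np.cross(r23, r13)
    norms = [np.linalg.norm(v) for v in (n1, n2, n3, n4)]
    if min(norms) < 1e-12:
        return 0.0
    n1, n2, n3, n4 = (v / s for v, s in zip((n1, n2, n3, n4), norms))
    omega = (math.asin(max(-1.0, min(1.0, float(n1 @ n2))))
             + math.asin(max(-1.0, min(1.0, float(n2 @ n3))))
             + math.asin(max(-1.0, min(1.0, float(n3 @ n4))))
             + math.asin(max(-1.0, min(1.0, float(n4 @ n1)))))
    sign = math.copysign(1.0, float(np.cross(p4 - p3, p2 - p1) @ r13))
    return omega * sign / (4.0 * math.pi)


def detect_backbone_tangles(chain: CGChain, link_threshold: float = 0.8,
                            window_nt: int = 2, proximity: float = 7.0
                            ) -> List[Finding]:
    """Entangled backbone windows via the discrete Gauss linking number.

    Every pair of non-adjacent ``window_nt``-nucleotide backbone windows
    whose beads come within ``proximity`` Å is closed with a far-point
    virtual closure and their linking number computed; |link| >=
    ``link_threshold`` flags a tangle.  Overlapping offending pairs merge
    into one finding.
    """
    n = chain.n_nt
    if n < 2 * window_nt + 2:
        return []
    windows: List[Tuple[Tuple[int, ...], np.ndarray]] = []
    last_start = n - window_nt + 1 if not chain.circular else n
    for w in range(1, last_start):
        nts = tuple((w - 1 + k) % n + 1 for k in range(window_nt))
        pts = []
        for nt in nts:
            pts.append(chain.coords[CGChain.bead_index(nt, "P")])
            pts.append(chain.coords[CGChain.bead_index(nt, "S")])
        windows.append((nts, np.array(pts)))

    hits: List[Tuple[int, int, float]] = []
    for a in range(len(windows)):
        for b in range(a + 1, len(windows)):
            nts_a, pa = windows[a]
            nts_b, pb = windows[b]
            sep = _chain_separation(nts_a, nts_b, n, chain.circular)
            if sep < 2:
                continue
            dmin = np.min(np.linalg.norm(pa[:, None] - pb[None], axis=-1))
            if dmin > proximity:
                continue
            ca, cb = _close_windows(pa, pb)
            link = abs(gauss_linking_number(ca, cb))
            if link >= link_threshold:
                hits.append((a, b, link))
    if not hits:
        return []
    # merge hits whose windows overlap on both sides
    findings: List[Finding] = []
    used = [False] * len(hits)
    for k, (a, b, link) in enumerate(hits):
        if used[k]:
            continue
        group = {k}
        changed = True
        while changed:
            changed = False
            for m, (a2, b2, _) in enumerate(hits):
                if m in group or used[m]:
                    continue
                if any(_overlap(windows[hits[g][0]][0], windows[a2][0])
                       and _overlap(windows[hits[g][1]][0], windows[b2][0])
                       for g in group):
                    group.add(m)
                    changed = True
        for m in group:
            used[m] = True
        res = set()
        sev = 0.0
        for m in group:
            aa, bb_, lk = hits[m]
            res.update(windows[aa][0])
            res.update(windows[bb_][0])
            sev = max(sev, lk)
        findings.append(Finding("backbone_tangle", tuple(sorted(res)), sev,
                                f"|linking number| = {sev:.2f}"))
    return findings


def _chain_separation(nts_a, nts_b, n, circular) -> int:
    best = None
    for x in nts_a:
        for y in nts_b:
            d = abs(x - y)
            if circular:
                d = min(d, n - d)
            d -= 1  # nucleotides strictly between the windows
            best = d if best is None else min(best, d)
    return best


def _closure_vector(win: np.ndarray, other: np.ndarray) -> Tuple[np.ndarray, bool]:
    """Closure offset direction for one window and whether it is forced.

    A bent window must close through its opening (the side of the start-end
    gap), otherwise the return path sweeps back across the arc; that
    direction is "forced".  A nearly straight window closes laterally
    (perpendicular to its chord), which leaves a free sign choice.
    """
    s0, s1 = win[0], win[-1]
    centroid = win.mean(axis=0)
    gap = 0.5 * (s0 + s1) - centroid
    if np.linalg.norm(gap) > 0.5:
        return gap / np.linalg.norm(gap), True
    chord = s1 - s0
    v = centroid - other.mean(axis=0)
    v = v - (v @ chord) * chord / max(chord @ chord, 1e-12)
    if np.linalg.norm(v) < 1e-6:
        v = np.cross(chord, other[-1] - other[0])
    if np.linalg.norm(v) < 1e-6:
        ref = np.array([0.0, 0.0, 1.0])
        if abs(chord @ ref) > 0.9 * np.linalg.norm(chord):
            ref = np.array([0.0, 1.0, 0.0])
        v = np.cross(chord, ref)
    return v / np.linalg.norm(v), False


def _close_windows(pa: np.ndarray, pb: np.ndarray, reach: float = 500.0
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Close both window polylines with distant return paths.

    Each return detours through two far waypoints offset sideways from the
    window.  When the two chosen offsets point the same way the far return
    paths would interfere (and spuriously cancel the linking number), so the
    free (lateral) one is flipped.
    """
    va, forced_a = _closure_vector(pa, pb)
    vb, forced_b = _closure_vector(pb, pa)
    if va @ vb > 0.3:
        if not forced_b:
            vb = -vb
        elif not forced_a:
            va = -va
    ca = np.vstack([pa, pa[-1] + reach * va, pa[0] + reach * va])
    cb = np.vstack([pb, pb[-1] + reach * vb, pb[0] + reach * vb])
    return ca, cb


def _overlap(nts1, nts2) -> bool:
    return bool(set(nts1) & set(nts2))


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------

def qc_report(chain: CGChain, pt: Optional[PairTable] = None,
              angle_min: float = 60.0, clash: float = 3.0,
              link_threshold: float = 0.8, min_loop_len: int = 15
              ) -> TopologyReport:
    """Run all four defect detectors and merge their findings."""
    findings: List[Finding] = []
    if pt is not None:
        findings += detect_template_free_loops(chain, pt, min_len=min_loop_len)
    findings += detect_backbone_tangles(chain, link_threshold=link_threshold)
    findings += detect_base_collisions(chain, clash=clash)
    findings += detect_sharp_twists(chain, angle_min=angle_min)
    return TopologyReport(findings)
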