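"""One-off fit of the helical placement constants in circfold.fixtures.

Optimizes the template pose (Euler angles), backbone radius, complementary
strand phase/offset and helical rise/twist so that a single rigid nucleotide
template repeated by helical symmetry gives a physically sensible A-form-like
duplex: continuous backbone (S-P ~ 3.9 Å, O3'-P ~ 1.6 Å), paired
Watson-Crick-edge beads ~ 3 Å apart, and no steric overlap.  The resulting
numbers are frozen as module constants in circfold/fixtures.py.

Run:  python scripts/fit_geometry.py
"""
import math
import numpy as np
from scipy.optimize import minimize

import circfold.fixtures as fx
from circfold.structure_io import map_to_cg


def set_params(x):
    fx.POSE_EULER = (x[0], x[1], x[2])
    fx.R_BB = x[3]
    fx.PHI2 = x[4]
    fx.Z2 = x[5]
    fx.TWIST = x[6]
    fx.RISE = x[7]
    fx.nucleotide_template.cache_clear()
    fx.cg_template.cache_clear()


def metrics():
    s = fx.build_single_helix("GGGGGG")
    cg = map_to_cg(s)
    c = cg.coords
    sp = np.mean([np.linalg.norm(c[5*i+1] - c[5*(i+1)]) for i in range(5)])
    o3p = np.mean([np.linalg.norm(s.residues[i].atoms["O3'"] -
                                  s.residues[i+1].atoms["P"]) for i in range(5)])
    # intrastrand sterics between non-adjacent residues
    pts = [np.array(list(r.atoms.values())) for r in s.residues]
    min_intra = min(np.linalg.norm(pts[i][:, None] - pts[j][None], axis=-1).min()
                    for i in range(6) for j in range(i + 2, 6))
    # adjacent-residue sterics, excluding the O3'-P linkage neighborhood
    adj = []
    for i in range(5):
        r1, r2 = s.residues[i].atoms, s.residues[i+1].atoms
        for n1, p1 in r1.items():
            for n2, p2 in r2.items():
                if {n1, n2} & {"O3'", "P", "OP1", "OP2", "O5'"}:
                    continue
                adj.append(np.linalg.norm(p1 - p2))
    min_adj = min(adj)
    s1, s2 = fx.duplex_strands("GCGC")
    cg1, cg2 = map_to_cg(s1), map_to_cg(s2)
    b1b1 = np.mean([np.linalg.norm(cg1.coords[5*k+2] - cg2.coords[5*(3-k)+2])
                    for k in range(4)])
    A = np.array([p for r in s1.residues for p in r.atoms.values()])
    B = np.array([p for r in s2.residues for p in r.atoms.values()])
    min_inter = np.linalg.norm(A[:, None] - B[None], axis=-1).min()
    return sp, o3p, min_intra, min_adj, b1b1, min_inter


def objective(x):
    set_params(x)
    try:
        sp, o3p, min_intra, min_adj, b1b1, min_inter = metrics()
    except Exception:
        return 1e6
    pen = 0.0
    pen += 25 * (sp - 3.9) ** 2
    pen += 60 * (o3p - 1.6) ** 2
    pen += 10 * (b1b1 - 3.0) ** 2
    pen += 80 * max(0.0, 2.4 - min_intra) ** 2
    pen += 80 * max(0.0, 2.0 - min_adj) ** 2
    pen += 80 * max(0.0, 2.4 - min_inter) ** 2
    return pen


x0 = np.array([0.0, 0.0, 0.0, 9.4, math.radians(150.0), 0.0,
               math.radians(32.7), 2.81])
# frozen solution (objective ~ 6.96); start near it to reproduce quickly
x0 = np.array([-0.24162289, -0.24917617, -0.70505652, 6.63346877,
               1.64571160, -0.34809763, 0.46169484, 5.37316493])
best = None
rng = np.random.default_rng(7)
for trial in range(40):
    xs = x0 + rng.normal(0, [0.6, 0.6, 0.6, 0.8, 0.8, 1.0, 0.05, 0.25], 8) \
        if trial else x0.copy()
    res = minimize(objective, xs, method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-5, "fatol": 1e-8})
    if best is None or res.fun < best.fun:
        best = res
        print(trial, res.fun)
set_params(best.x)
print("objective:", best.fun)
print("metrics (sp, o3p, min_intra, min_adj, b1b1, min_inter):", metrics())
names = ["POSE_EULER_A", "POSE_EULER_B", "POSE_EULER_C", "R_BB", "PHI2", "Z2",
         "TWIST", "RISE"]
for n, v in zip(names, best.x):
    print(f"{n} = {v!r}")
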