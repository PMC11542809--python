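import numpy as np
import pytest

from circfold import (
    GeometryError,
    build_fragment_library,
    fixtures,
    geometry_cleanup,
    kabsch_superpose,
    map_to_cg,
    rebuild_all_atom,
    write_pdb,
)
from circfold.rebuild import FRAGMENT_BEND_VARIANTS, FRAGMENT_SPIN_VARIANTS
from circfold.structure_io import AllAtomStructure, Residue

from conftest import quaternion_rmsd


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestKabsch:
    def test_identity(self):
        x = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        sup = kabsch_superpose(x, x)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(sup.translation, 0.0, atol=1e-9)

    def test_exact_recovery_of_rigid_transform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 3)) * 5
        q = _random_rotation(rng)
        t = rng.normal(size=3) * 10
        y = (x - t) @ q  # x = q @ y + t
        sup = kabsch_superpose(x, y)
        assert sup.rmsd < 1e-9

    def test_square_with_displaced_corner_matches_oracle(self):
        x = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        y = x.copy()
        y[2, 2] = 1.0
        assert kabsch_superpose(x, y).rmsd == pytest.approx(
            quaternion_rmsd(x, y), abs=1e-9)

    def test_oracle_agreement_100_random_sets(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(4, 21))
            x = rng.normal(size=(n, 3)) * rng.uniform(0.5, 10)
            y = rng.normal(size=(n, 3)) * rng.uniform(0.5, 10)
            assert kabsch_superpose(x, y).rmsd == pytest.approx(
                quaternion_rmsd(x, y), abs=1e-9)

    def test_symmetry_and_joint_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 3))
        y = rng.normal(size=(6, 3))
        r0 = kabsch_superpose(x, y).rmsd
        assert kabsch_superpose(y, x).rmsd == pytest.approx(r0, abs=1e-9)
        q = _random_rotation(rng)
        t = rng.normal(size=3)
        assert kabsch_superpose(x @ q.T + t, y @ q.T + t).rmsd \
            == pytest.approx(r0, abs=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(GeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(GeometryError):
            kabsch_superpose(line, line)

    def test_rotation_is_proper_orthonormal(self):
        rng = np.random.default_rng(3)
        sup = kabsch_superpose(rng.normal(size=(5, 3)),
                               rng.normal(size=(5, 3)))
        assert np.allclose(sup.rotation.T @ sup.rotation, np.eye(3),
                           atol=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)


class TestFragmentLibrary:
    def test_cg_images_consistent(self):
        lib = build_fragment_library()
        for base, frags in lib.fragments.items():
            for frag in frags:
                res = Residue(1, base, {n: frag.atom_coords[i]
                                        for i, n in enumerate(frag.atom_names)})
                cg = map_to_cg(AllAtomStructure([res]))
                assert np.allclose(cg.coords, frag.cg_image, atol=1e-9)

    def test_coverage_and_count(self):
        lib = build_fragment_library()
        assert set(lib.fragments) == set("ACGU")
        assert all(len(v) >= 1 for v in lib.fragments.values())
        assert lib.size == (len(FRAGMENT_SPIN_VARIANTS)
                            * len(FRAGMENT_BEND_VARIANTS) * 4)


class TestRebuild:
    def test_exact_round_trip_on_library_fragments(self, hairpin):
        _, _, chain, _ = hairpin
        lib = build_fragment_library()
        rebuilt = rebuild_all_atom(chain, lib)
        cg_back = map_to_cg(rebuilt)
        per_nt = [kabsch_superpose(chain.coords[5 * i:5 * i + 5],
                                   cg_back.coords[5 * i:5 * i + 5]).rmsd
                  for i in range(chain.n_nt)]
        assert max(per_nt) < 1e-6

    def test_round_trip_on_simulation_snapshots(self, hairpin, params):
        """map_to_cg(rebuild(chain)) stays within the frozen 0.8 Å per-nt
        tolerance on thermally perturbed snapshots."""
        from circfold import SimulationState, System, langevin_step
        from circfold.dynamics import maxwell_velocities
        from circfold.secondary_structure import pair_restraints
        _, _, chain, pt = hairpin
        sysm = System(chain, params, pair_restraints(pt))
        rng = np.random.default_rng(8)
        state = SimulationState(chain.coords.copy(),
                                maxwell_velocities(chain.masses, 300.0, rng),
                                chain.masses.copy())
        _, forces = sysm.energy_forces(state.positions)

        def force_fn(x):
            return sysm.energy_forces(x)[1]

        lib = build_fragment_library()
        for step in range(2000):
            state, forces = langevin_step(state, forces, 1.0, 300.0, 0.01,
                                          rng, force_fn)
            if (step + 1) % 500 == 0:
                snap = chain.with_coords(state.positions)
                back = map_to_cg(rebuild_all_atom(snap, lib))
                per_nt = [kabsch_superpose(
                    snap.coords[5 * i:5 * i + 5],
                    back.coords[5 * i:5 * i + 5]).rmsd
                    for i in range(chain.n_nt)]
                assert max(per_nt) < 0.8

    def test_sequence_and_count_preserved(self, hairpin):
        seq, _, chain, _ = hairpin
        rebuilt = rebuild_all_atom(chain)
        assert rebuilt.sequence == seq
        assert [r.number for r in rebuilt.residues] == list(range(1, 13))
        write_pdb(rebuilt)  # valid PDB output

    def test_unknown_base_rejected(self, hairpin):
        _, _, chain, _ = hairpin
        from circfold.structure_io import CGChain
        bad = CGChain("T" + chain.sequence[1:], chain.coords, chain.masses)
        with pytest.raises(KeyError):
            rebuild_all_atom(bad)


def _dinucleotide(gap):
    """Two template residues with the O3'-P linkage set to ``gap`` Å.

    The second residue's pose (offset direction + rotation) was chosen once
    so that, at the 1.6 Å bonded gap, no non-linkage atom pair comes within
    clash range (verified min distance 3.7 Å).
    """
    direction = np.array([-0.92412833, -0.23202274, 0.30356595])
    axis = np.array([0.40010354, -0.69984037, -0.59172681])
    angle = 0.80968744
    names, local = fixtures.nucleotide_template("G")
    r1 = Residue(1, "G", {n: local[i].copy() for i, n in enumerate(names)})
    o3 = r1.atoms["O3'"]
    p_local = local[list(names).index("P")]
    c, s = np.cos(angle), np.sin(angle)

    def rot(v):
        return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1 - c)

    offset = o3 + gap * direction
    r2_atoms = {n: rot(local[i] - p_local) + offset
                for i, n in enumerate(names)}
    r2 = Residue(2, "G", r2_atoms)
    return AllAtomStructure([r1, r2])


class TestGeometryCleanup:
    def test_satisfied_structure_unchanged(self):
        s = _dinucleotide(1.6)
        # verify the construction truly has no clashes first
        cleaned = geometry_cleanup(s, steps=100)
        for r0, r1 in zip(s.residues, cleaned.residues):
            for n in r0.atoms:
                assert np.linalg.norm(r0.atoms[n] - r1.atoms[n]) < 1e-6

    def test_backbone_gap_shrinks(self):
        s = _dinucleotide(4.0)
        cleaned = geometry_cleanup(s, steps=50)
        d0 = np.linalg.norm(s.residues[0].atoms["O3'"]
                            - s.residues[1].atoms["P"])
        d1 = np.linalg.norm(cleaned.residues[0].atoms["O3'"]
                            - cleaned.residues[1].atoms["P"])
        assert d1 < d0

    def test_clash_separation_grows(self):
        names, local = fixtures.nucleotide_template("G")
        r1 = Residue(1, "G", {n: local[i].copy() for i, n in enumerate(names)})
        # second residue far away except one atom clashing at 1.0 Å
        shift = np.array([60.0, 0.0, 0.0])
        r2_atoms = {n: local[i] + shift for i, n in enumerate(names)}
        r2_atoms["N1"] = r1.atoms["N7"] + np.array([1.0, 0.0, 0.0])
        r2 = Residue(2, "G", r2_atoms)
        s = AllAtomStructure([r1, r2])
        cleaned = geometry_cleanup(s, steps=30)
        d0 = np.linalg.norm(s.residues[1].atoms["N1"]
                            - s.residues[0].atoms["N7"])
        d1 = np.linalg.norm(cleaned.residues[1].atoms["N1"]
                            - cleaned.residues[0].atoms["N7"])
        assert d1 > d0

    def test_motion_cap(self):
        s = _dinucleotide(8.0)
        cleaned = geometry_cleanup(s, steps=500)
        for r0, r1 in zip(s.residues, cleaned.residues):
            for n in r0.atoms:
                assert np.linalg.norm(r0.atoms[n] - r1.atoms[n]) <= 2.0 + 1e-9
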