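# Methods

## The problem

Circular RNAs (circRNAs) are covalently closed: the 3' end of the transcript
is back-spliced onto its 5' end, so the molecule has no free termini and its
secondary structure is a closed chain whose dot-bracket string begins and
ends at the back-splicing junction (BSJ). Structure generators built for
linear RNA (template assembly from fragment libraries) can produce an
initial 3D model of the *linear* counterpart, but that model (a) has two
free ends that must be joined, and (b) frequently contains locally
irrational geometry — long loops built from one repeated template pose,
entangled backbone segments, backbone bonds threaded between stacked bases,
and abnormally sharp backbone bends.

`circfold` turns such a linear model into circular 3D models with a
four-stage coarse-grained (CG) molecular-dynamics workflow, and provides
detectors that audit any model for the four defect classes.

## Coarse-grained representation

Five beads per nucleotide: `P` on the phosphorus atom, `S` on C4', and
three base beads at the mass-weighted centers of the three edges of the
nucleobase (B1 = Watson-Crick edge, B2 = Hoogsteen/C-H edge, B3 = sugar
edge). The base-edge atom partition is fixed in a versioned table
(`structure_io.BASE_GROUPS`); the exact membership of each edge group is a
package convention — the three-edge idea is standard, the atom lists are
ours. Bead masses are summed heavy-atom masses; hydrogens are ignored
throughout.

## Surrogate force field

The published CG force field this workflow emulates is parameterized
elsewhere and not reproduced here; `circfold` uses a documented surrogate
with the same controllable elements:

| term | form | default |
| --- | --- | --- |
| bond | k_b (b − b0)² | k_b = 20 kcal/mol/Å² |
| angle | k_θ (θ − θ0)² | k_θ = 10 kcal/mol/rad² |
| torsion | k_φ (1 + cos(nφ − δ)), δ = nφ0 − π | k_φ = 1 kcal/mol, n = 1 |
| pairing | −ε_p exp(−(r − r_p)²/2σ_p²) on B1–B1 | ε_p = 4 (WC) / 2.5 (wobble) / 2 (noncanonical), σ_p = 1 Å |
| excluded volume | ε_ev[(r_ev/r)¹² − 2(r_ev/r)⁶ + 1], r < r_ev | r_ev = 3.5 Å, ε_ev = 1 |
| end closure | k (d − 3.8 Å)², d = \|P₁ − S_N\| | k ramped 0.001 → 5 kcal/mol/Å² |

Every equilibrium geometry value (b0, θ0, φ0 per bonded-term family, and
the pairing minimum r_p) is *measured once* from an idealized helix fixture
and frozen in the versioned file `src/circfold/data/forcefield_v1.yaml`
(regenerate with `scripts/fit_forcefield.py`). Bonded terms cover the
backbone (P–S, S–P', P–S–P', S–P'–S', the two backbone virtual torsions),
the base attachment (S–B1 bond, P–S–B1 / B1–S–P' / S–B1–B2 / S–B1–B3
angles, the P–S–B1–B2 torsion) and the rigid base triangle (B1–B2–B3
bonds). Nonbonded exclusions follow the standard 1-2/1-3 rule (beads within
two bonded edges).

Two parameter choices deviate from the first sketch of this design and are
deliberate:

* **r_ev = 3.5 Å (not 4 Å).** The fixture-fitted attractive minima of the
  model are all below 4 Å (paired B1–B1 3.72 Å, bonded S–P 3.97 Å, closure
  target 3.8 Å). A 4 Å repulsive floor would push against every native
  contact the model is supposed to form; the excluded volume must sit below
  the model's own minima to be a pure steric term.
* **The restrained end pair (P₁, S_N) is EV-excluded while the closure
  restraint is active.** After circularization this pair is bonded and
  excluded anyway; repelling it during closure is an inconsistency, not
  physics.

Circular topology is purely a flag: every bonded-term family wraps across
the (N, 1) edge with the same parameters as interior connections, which is
exactly what the covalent BSJ means.

## Dynamics

Langevin dynamics (NVT) with the BAOAB splitting, Δt = 1 fs, friction
γ = 0.01 fs⁻¹ by default. Units are Å / fs / kcal/mol / g/mol with a single
force-to-acceleration constant (4.184·10⁻⁴) and k_B = 1.9872·10⁻³
kcal/mol/K. Forces are fully analytic (verified against central finite
differences to better than 10⁻⁴ relative).

**End closure** anneals temperature linearly 500 → 300 K while the end
restraint ramps geometrically 0.001 → 5 kcal/mol/Å² and the pairing
interactions are staged through scale factors 0.01 / 0.1 / 1.0 over equal
thirds (unfold, then refold). The k-ramp completes at 80% of the run and
holds at its maximum thereafter: the closed conformation is selected by
clustering the final 10% of the trajectory, and that selection window must
be sampled under the full-strength restraint — with a ramp that only
reaches 5 kcal/mol/Å² at the last instant, the selected structure
systematically sits 0.5–0.8 Å too far open. Run length scales with the
initial end separation (10 ns at ≤20 Å to 50 ns at ≥200 Å, linear,
clamped).

**Replica exchange** uses a geometric temperature ladder (default 10 rungs,
280–460 K), Metropolis neighbor swaps every 1000 steps alternating even/odd
rung pairs. Accepted swaps exchange configurations between rungs with
velocities rescaled by √(T_new/T_old) — the rung-major implementation of
"temperatures swap, configurations persist". The friction coefficient, the
exchange interval and the swap bookkeeping are conventional choices; they
are not prescribed by the protocol this package follows.

## Ensemble reduction

Production protocol: 100 ns per replica, three independent runs from
different closed starts when available (fewer starts → fewer runs, logged),
snapshots from the trailing half at 100 ps intervals — 3 × 10 × 500 =
15,000 snapshots. The lowest-energy 10% go to greedy quality-threshold
clustering on CG-backbone (P+S) RMSD after Kabsch superposition; the
centroids of the up-to-five largest clusters become the models. Ties break
deterministically (earlier time, then lower replica id; lowest index for
cluster seeds), which makes the whole pipeline bitwise reproducible under
fixed seeds.

The production clustering cutoff default is 5 Å. The desk profile
(`time_scale = 1e-3`, 2 replicas, 1 run) uses 1 Å because a 100 ps run
explores a far narrower conformational spread (median pairwise backbone
RMSD ≈ 1.6 Å in the desk ensemble); the cutoff is configuration-exposed
either way.

## All-atom reconstruction and cleanup

Each nucleotide is rebuilt independently: candidate all-atom fragments are
rigidly superposed (Kabsch) onto the nucleotide's five beads and the
best-fitting fragment's atoms are placed with the winning transform. The
fragment library is generated from idealized nucleotide geometry (the
chemical-component dictionary conformers shipped with biotite, backbone
unified across bases) gridded over the two *soft* internal coordinates of
the five-bead geometry: the base-triangle spin about the sugar→WC-edge axis
(21 values, 15° apart) and the P–S–B1 bend (3 values) — 252 fragments. The
grid was chosen against the thermal spread of those coordinates at 300 K;
the measured worst-case round-trip error (map → rebuild → map) on thermal
snapshots is 0.69 Å per-nucleotide bead RMSD.

Backbone continuity between residues is then restored best-effort by
`geometry_cleanup`: limited steepest descent on inter-residue O3'–P bond
restraints (target 1.6 Å) plus a short-range heavy-atom clash term
(< 2.5 Å; the chemical 1-2/1-3 neighborhood across the phosphodiester
linkage is exempt), with a hard 2 Å cap on per-atom motion. This is a local
polish, not a molecular-mechanics minimization.

## Topology quality control

All four detectors run on CG beads (all-atom models are mapped first):

* **Template-free loop** — unpaired runs ≥ 15 nt in which consecutive local
  descriptors (|P–S|, |S–P'|, virtual torsion P–S–P'–S') agree pairwise
  within 0.2 Å / 5°.
* **Sharp twist** — backbone virtual angles below 60°; consecutive acute
  angles merge into one finding.
* **Base collision** — a backbone bond from a distant part of the chain
  crossing both base planes of a sequence-adjacent nucleotide pair inside
  the triangle footprints and approaching a base centroid within 3 Å;
  findings merge per base slab.
* **Backbone tangle** — pairs of 2-nt backbone windows within 7 Å whose
  virtually closed polylines have |Gauss linking number| ≥ 0.8. Each open
  window closes through two far waypoints offset to the side of the
  window's opening (bent windows) or laterally (straight windows), with the
  two windows' offsets forced apart when they would interfere — closure
  paths that sweep back across a window or coincide silently cancel the
  linking number.

The original defect census was done by visual inspection, so any
operationalization is a formalization choice; the thresholds above are
calibrated so an ideal-helix fixture is clean while each planted-defect
fixture fires exactly its own detector, and all of them are
configuration-exposed.

BSJ typing: the junction edge (N, 1) is *helix* when its two flanking
nucleotides pair with circularly adjacent partners (the stem spans the
junction); otherwise the type follows the closing-pair count of the loop
containing the edge (1 → hairpin, 2 → internal, ≥3 → junction; a fully
unpaired circle is reported "unstructured" and the pipeline proceeds).

## Synthetic fixtures: what they are and are not

All test inputs are generated programmatically. A single rigid nucleotide
template repeated by helical symmetry yields the duplex/hairpin/dumbbell
fixtures; the placement constants were fitted once (see
`scripts/fit_geometry.py`) so that the backbone is continuous (O3'–P ≈
1.6 Å) and paired WC-edge beads sit a few Å apart without steric overlap.
Because the template's internal conformation is the idealized CCD one, the
resulting helix is stretched relative to crystallographic A-form (rise
5.37 Å/nt). The fixtures therefore exercise the *protocol* — closure,
sampling, clustering, reconstruction, defect detection — on self-consistent
geometry; passing tests say nothing about prediction accuracy against
experimental circRNA structures, which would require the external 2D/3D
generators and scoring functions that are out of scope here.

Planted-defect fixtures are explicit bead-level constructions, each
engineered (and verified) to contain exactly one defect of one class.

## Problem sizes used in the shipped tests

The test suite and the acceptance script run the desk profile: 24-nt
fixtures, `time_scale = 1e-3` (100 ns → 100 ps; snapshot intervals scale
identically), 2 replicas, 1 run. These sizes are the package's default
verification profile; the production profile (full durations, 10 replicas,
3 runs) is selected purely through the run configuration.

## Known limitations

* The force field is a surrogate: it preserves the protocol's controllable
  structure (scalable pairing, closure restraint, circular wiring), not any
  published parameter tables; energies are not comparable across force
  fields.
* Pseudoknots are rejected; modified nucleotides, multi-chain complexes and
  mmCIF input are out of scope.
* Desk-scale runs cannot fold a hairpin to equilibrium; the closure-stage
  equilibrium distance (~4.0 Å vs the 3.8 Å restraint target) includes
  residual chain tension that a production-length run would relax further.
* `geometry_cleanup` is a local repair; rebuilt models can retain imperfect
  stereochemistry that a full-atom refinement program would fix.
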