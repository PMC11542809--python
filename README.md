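# circfold

Coarse-grained 3D structure prediction and topology auditing for circular
RNAs.

Circular RNAs (circRNAs) are covalently closed transcripts: back-splicing
joins the 3' end to the 5' end, so the molecule is a closed chain and its
secondary structure is written as a dot-bracket string whose two ends meet
at the back-splicing junction (BSJ). 3D models of circRNAs are usually
bootstrapped from a model of the *linear* counterpart, which leaves two
problems: the free ends must be covalently joined in 3D, and
template-assembled models often contain locally irrational geometry.
`circfold` addresses both for structural-RNA researchers who have a
sequence, a circular secondary structure, and an initial linear 3D model.

## What it does

Given sequence + circular dot-bracket + initial PDB model(s), the pipeline
runs four stages:

1. **Input preparation** — map the all-atom model to a five-bead-per-
   nucleotide representation (P on the phosphorus, S on C4', three beads on
   the mass centers of the base's three interacting edges), parse the
   circular secondary structure, classify the BSJ context
   (helix-/hairpin-/internal-/junction-circular), audit the input.
2. **End closure** — simulated-annealing Langevin dynamics (500 → 300 K)
   with a harmonic restraint E = k(d − b₀)², b₀ = 3.8 Å, between bead P of
   nucleotide 1 and bead S of nucleotide N, its force constant ramped
   0.001 → 5.0 kcal/mol/Å² while base pairing is staged through
   0.01 / 0.1 / 1.0 of its strength (unfold, then refold).
3. **Structure prediction** — circularize the bonded topology across the
   junction and sample with temperature-ladder replica-exchange MD
   (default 10 replicas, 280–460 K, Metropolis neighbor swaps); collect
   snapshots from the trailing half of each replica, keep the 10% with the
   lowest potential energy, cluster by backbone RMSD (quality-threshold)
   and take the centroids of the largest clusters (default five models).
4. **Model refinement** — rebuild all-atom coordinates by single-nucleotide
   fragment matching and polish backbone continuity/clashes with a bounded
   steepest-descent cleanup; write PDB models plus reports.

Independently of the pipeline, `circfold qc` detects the four classes of
locally irrational topology in any RNA 3D model: template-free loops
(long loops repeating one pose), backbone tangles (Gauss-linking of
backbone windows), base collisions (backbone threading between stacked
bases) and sharp twists (acute backbone angles).

The CG energy model is a documented surrogate with harmonic bonded terms, a
Gaussian base-pairing well acting between Watson-Crick-edge beads and a
WCA-style excluded volume; every equilibrium value is fitted from the
package's ideal-helix fixture and shipped in a versioned parameter file.
See `docs/methods.md` for the model, parameters and design decisions.

## Worked example

Generate a toy input — a 24-nt chain with hairpin secondary structure whose
3D conformation is an open arc with the ends ~27 Å apart — and predict:

```
$ circfold fixture --kind open_hairpin -o demo
demo/open_hairpin.fasta
demo/open_hairpin.db
demo/open_hairpin.pdb

$ cat demo/config.toml
[input]
sequence = "demo/open_hairpin.fasta"
structure = "demo/open_hairpin.db"
pdbs = ["demo/open_hairpin.pdb"]
[simulation]
time_scale = 1e-3   # desk scale: 100 ns -> 100 ps
replicas = 2
runs = 1
[ensemble]
cluster_cutoff = 1.0
[output]
directory = "demo/out"
[seeds]
master = 7

$ circfold predict -c demo/config.toml
demo/out/models/model_01.pdb
demo/out/models/model_02.pdb
demo/out/models/model_03.pdb
demo/out/models/model_04.pdb
demo/out/models/model_05.pdb
5 model(s) written; defects in models: 0
```

Five models are the centroids of the five largest conformational clusters;
the stderr line reports the locally-irrational-topology count over all
emitted models (here zero). `demo/out/` also contains the ensemble index,
the cluster table, per-stage energy series, QC reports and a manifest with
every seed used. In every model the closed junction stays near its
equilibrium: mapping `model_01.pdb` back to beads gives a P₁–S_N distance
of ≈ 3.8 Å, right at the closure target.

Check any model for irrational topology:

```
$ circfold qc demo/out/models/model_01.pdb --ss demo/open_hairpin.db
kind    count
template_free_loop      0
backbone_tangle 0
base_collision  0
sharp_twist     0
```

## Layout

```
src/circfold/
  structure_io.py        PDB I/O, five-bead CG mapping
  secondary_structure.py circular dot-bracket, loops, BSJ typing
  forcefield.py          surrogate CG energy/forces, circular topology
  dynamics.py            BAOAB Langevin, annealing closure, REMD
  ensemble.py            snapshot schedule, selection, QT clustering
  rebuild.py             Kabsch, fragment library, all-atom rebuild, cleanup
  topology_qc.py         the four defect detectors
  fixtures.py            deterministic toy structures (incl. planted defects)
  pipeline.py            config + four-stage workflow
  cli.py                 circfold predict | qc | fixture | rmsd
  data/forcefield_v1.yaml  versioned force-field parameters
```

The CG pseudo-atom PDB dialect: beads are written as ATOM records named
`P`, `S`, `B1`, `B2`, `B3` with the residue name set to the base letter.

Out of scope: 2D structure prediction, generation of the initial linear 3D
model, third-party refinement/scoring, pseudoknots, modified nucleotides,
multi-chain complexes.
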