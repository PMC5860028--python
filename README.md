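# motifdock

Global rigid-body docking of peptide **linear motifs** to free receptor
structures, via motif-guided fragment libraries and FFT correlation.

Many transient protein–protein interactions are mediated by a short linear
motif — e.g. cyclins recognize the `RXL` motif, where `X` is any residue.
Motif regions adopt only a small ensemble of backbone conformations, which
makes the otherwise flexible peptide-docking problem tractable for rigid-body
FFT sampling: harvest the conformations that known structures adopt at motif
matches, then dock each one exhaustively.

The pipeline has four stages:

1. **Fragment library** (`motifdock.motiflib`): compile the motif, scan a
   structure database for matches (excluding chains with > 30% sequence
   identity to the target), and steer the library into a 100–1000 member
   window — generalizing the motif with wildcards when matches are scarce,
   or restricting it with fixed flanking residues from the peptide context
   when they are abundant. Motifs shorter than 5 residues are wildcard-padded.
2. **Fragment clustering**: greedy clustering at a stringent 0.5 Å superposed
   backbone RMSD radius; up to 25 cluster centers are retained.
3. **FFT docking** (`motifdock.fftdock`): the receptor is discretized into a
   repulsive core, an attractive surface shell and a Coulombic potential with
   distance-dependent dielectric; each rotated fragment is scored over all
   grid translations at once by FFT cross-correlation

   `S(t) = w_rep (rep ⋆ occ)(t) + w_att (att ⋆ occ)(t) + w_elec (elec ⋆ q)(t)`

   keeping one pose per rotation and the best 250 per fragment. A named
   "electrostatics-favored" weight set up-weights the Coulomb term for
   interactions dominated by charge complementarity.
4. **Selection and evaluation** (`motifdock.select`): pooled poses are
   greedy-clustered at 3.5 Å ligand RMSD in the receptor frame, ranked by
   cluster size (a proxy for basin breadth), filtered against user-declared
   domain–domain interfaces, and — when a native complex is given — graded
   with the peptide acceptance criterion: backbone RMSD ≤ 4.0 Å to the native
   peptide after receptor superposition.

`motifdock.fixtures` generates every input synthetically (a slab receptor
with a geometrically and electrostatically complementary groove, a planted
native pose whose optimality is verified by exhaustive enumeration, and
fragment databases with exact planted match counts), so the full protocol
runs and is tested without downloading any structure.

## Worked example

```sh
motifdock make-fixtures --out fix --seed 1
motifdock run-all \
    --receptor fix/receptor.pdb --db fix/manifest.txt --motif KGRRL \
    --native-peptide fix/native_peptide.pdb \
    --out run --n-rotations 16 --seed 1
```

prints

```
pipeline complete: 19 ranked models under run
```

and `run/summary.tsv` begins

```
rank  member_count  fragment_id  e_rep     e_att       e_elec     e_total     rmsd_native
1     4             0            0.000000  -20.000000  -0.213348  -84.004525  0.590
2     4             0            0.000000  -17.000000  -0.062563  -35.768949  9.691
```

Rank 1 is the planted binding mode: no core overlap (`e_rep` 0), every
backbone atom in the attractive shell (`e_att` −20 over 20 atoms), the
strongest electrostatic complementarity, and 0.59 Å backbone RMSD to the
native peptide — well inside the 4.0 Å acceptance threshold
(`run/evaluation.json` reports `"best_rank_acceptable": 1`). Off-site
clusters score 30–50 energy units worse. Ranks are by cluster size with ties
broken by representative energy; with desk-scale rotation sets the acceptable
model is always reported and is the lowest-energy representative, but its
size rank can fall in the top handful rather than first (see
`docs/methods.md`).

The same stages are available separately (`build-library`, `dock`, `select`,
`evaluate`), reading and writing plain PDB/TSV files, and as library
functions.

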