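# Methods

## Problem and model

motifdock docks a peptide recognition motif to a free receptor structure as a
four-stage protocol: (1) build a library of backbone conformations harvested
at motif matches in a structure database, (2) cluster the library and keep up
to 25 representatives, (3) rigidly dock each representative by FFT
correlation of energy grids, (4) cluster and size-rank the pooled poses and,
when a native complex is available, grade them with the 4.0 Å
backbone-RMSD acceptance criterion.

The underlying assumption is the one that makes rigid-body sampling viable
for peptides at all: motif regions adopt a small ensemble of backbone
conformations, so docking each member of that ensemble rigidly is a good
surrogate for docking a flexible peptide.

## Motif search and library-size control

A motif is a string over the 20 one-letter codes plus `X` (wildcard). All
overlapping matches are reported. The library controller evaluates the match
count after identity filtering and then moves the pattern toward the
100–1000 window:

- **Padding**: motifs shorter than 5 residues are padded with wildcards at
  the C-terminus (`RXL` → `RXLXX`). The side is a policy (`pad_side`).
- **Generalize** (too few matches): convert the outermost fixed position not
  belonging to the user's original motif to a wildcard; if only original
  positions remain, convert the one whose residue type is rarest in the
  database, never dropping below two fixed positions. This preserves the
  motif's anchor residues longest.
- **Restrict** (too many matches): append a fixed residue taken from the
  peptide's actual flanking sequence, alternating C- then N-terminal; it
  therefore requires the peptide context and is skipped without it.

Moves stop on entering the window, running out of moves, revisiting a
pattern, or `max_iter`. The history of (pattern, count) pairs is recorded
and attached to the empty-library error when nothing is found.

**Sequence identity** uses a global alignment with match +1, mismatch 0,
linear gap −1, normalized by the shorter length. Because co-optimal
alignments under this scoring can differ in identity count, the value is
defined as the identity count of the alignment maximizing (score,
identities) lexicographically — deterministic and symmetric. Note that under
this gapped scoring two unrelated random sequences align at ≈ 0.30 identity,
so the default 0.30 exclusion threshold sits essentially at background: it
removes true homologs while keeping nearly everything unrelated (removal
requires *exceeding* the threshold).

## Clustering

Both fragment clustering (0.5 Å, superposed backbone RMSD over N, CA, C, O)
and pose clustering (3.5 Å, unsuperposed ligand RMSD in the receptor frame)
use the same greedy rule: repeatedly pick the element with the most
neighbors within the radius (ties: lowest input index), emit that cluster,
remove it. Fragment cluster centers are the greedy centers; pose cluster
representatives are the lowest-energy members. Pose similarity is deliberately
*not* superposed: superposition would erase binding-site location, which is
what pose clustering must distinguish. Superposition RMSD is computed by SVD
(Kabsch) with the determinant correction against reflections; near-zero
values are computed by applying the optimal rotation explicitly, avoiding the
cancellation error of the closed-form residual.

## Energy model and FFT docking

The receptor is discretized on a cubic grid (default 1.0 Å):

- **rep**: 1 inside a 1.8 Å core around any heavy atom (clash indicator);
- **att**: −1 in a 3.0 Å shell outside the core (surface-contact indicator);
- **elec**: Coulomb potential with distance-dependent dielectric ε(r) = 4r,
  distance capped below at one voxel and truncated at 12 Å. Charges are
  residue-level unit charges (Asp/Glu −1, Lys/Arg +1, His +0.1) on the
  canonical side-chain atom (CG/CD/NZ/NH1/ND1), falling back to CA when the
  atom is absent; fragment (backbone-only) charges sit on CA. No hydrogens
  are ever needed.

A rotated, centroid-centered fragment is deposited nearest-voxel onto
occupancy and charge grids. The score of every integer translation is the
weighted cross-correlation evaluated with real FFTs; per-term energies of a
selected pose are recomputed by direct summation over ligand atoms (exact,
and independent of the FFT path), so the decomposition
`e_total = w_rep·e_rep + w_att·e_att + w_elec·e_elec` is exact by
construction. One best wrap-free translation is kept per rotation
(preventing a single basin from flooding the pool), and the best 250 poses
per fragment are pooled. Ties always resolve to the lower rotation index and
lexicographically first voxel, making every stage deterministic.

**Weight sets.** The shipped sets are `standard` (w_rep 150, w_att 1,
w_elec 300) and `electrostatics-favored` (750, 1, 1500). The repulsive
coefficient is tied to the electrostatic one (w_rep = w_elec/2) because the
deepest possible electrostatic well per unit charge is 0.25·w_elec at the
1 Å distance cap: with a smaller w_rep a charged atom would profitably bury
itself in the receptor core next to an opposite charge. The
electrostatics-favored set multiplies the charge term (and with it the
clash guard) fivefold relative to the shape attraction, for interactions
dominated by polar contacts.

**Rotations.** Quasi-uniform rotation sets come from a super-Fibonacci
quaternion spiral — a deterministic low-discrepancy cover of SO(3) — with
the identity first and the seed applied as a fixed global rotation of the
remainder (same n and seed ⇒ identical set; nearest-neighbor angular
spacing has coefficient of variation ≈ 0.09 at n = 500). Desk-scale sets of
10–10³ rotations are the intended regime here; production-scale sampling
(10⁴–10⁵ rotations) is out of scope.

## Selection and evaluation

Clusters are ranked by member count (descending; ties by representative
energy, then formation order) and re-ranked consecutively after
interface-overlap removal, which drops any cluster whose representative
backbone comes within 5.0 Å of a user-declared other-domain interface
residue. `refine_representatives` is an explicit pass-through hook where a
force-field minimizer can be plugged in; by default it logs and returns its
input unchanged.

Evaluation superposes the model receptor onto the native receptor on common
CA atoms (matched by author residue number), applies that rigid motion to
each predicted peptide, and reports backbone RMSD to the native peptide with
no further superposition. A prediction is acceptable at ≤ 4.0 Å; the report
carries the best rank achieving it.

## Synthetic fixtures: what they emulate and what they do not

The fixture generator builds idealized extended-strand geometry with
*integer* atom coordinates (4.0 Å rise, unit-offset N/CA/C/O template) so
that, with the grid origin snapped to the same lattice, discretization is
exact: there is no rounding slop between continuous coordinates and voxels,
and planted optima can be verified by exhaustive enumeration.

- **Receptor**: a two-layer slab of strands with a groove that exactly fits
  the motif-length peptide, closed at both ends. Above the groove, one
  charge site per charged motif residue ("pendants", opposite charge, 2 Å
  above the planted CA) is recessed behind a collar of neutral atoms that
  blocks every distance-2 lattice approach except the one from the planted
  CA. Because the attractive shell is binary (any surface pose buries all 20
  backbone atoms in it), pocket recognition is carried by electrostatics;
  the pendant spacing replicates the motif's charged-position pattern, which
  for `KGRRL` ({0, 8, 12} Å) is non-palindromic, so only the in-register
  placement can make every charge contact at the minimal lattice distance.
  The planted pose is *not assumed* optimal: tests confirm it by direct
  (non-FFT) scoring over several rotation sets.
- **Database**: chains of random background sequence (excluding all fixed
  motif letters and all chargeable letters) with exactly the requested
  number of motif windows; each window carries the native backbone — drawn
  from two distinct planted conformers 0.63 Å apart, so fragment clustering
  has genuine structure — plus Gaussian jitter (default σ = 0.1 Å, small
  enough that jittered fragments voxelize identically to their conformer
  and all cluster centers remain groove-compatible).

What passing these tests shows: the machinery (search, size control,
clustering, FFT scoring, ranking, evaluation) is correct and deterministic,
and the score's global optimum is found and graded properly. What it does
not show: performance on real structures, where backbone geometry is
irregular, charges are not unit point charges, and the conformational
ensemble is not Gaussian jitter around two templates.

## Ranking power at desk scale

Cluster-size ranking estimates the breadth of a pose's basin of attraction
and needs dense rotational sampling to do so. The planted groove admits only
~15° of rotational slack, so with 12–24 quasi-uniform rotations the
near-native basin collects a couple of poses while occasionally two
spin-related rotations merge into a larger off-site cluster. In seed scans
the acceptable model ranks between 1 and 5 by size, is always inside the
reported top 20, and is always the lowest-energy representative; pure
energy ranking of the docked poses puts the planted pose first in every
scanned configuration. This mirrors the method's design point — production
runs spend hundreds of CPU-hours precisely to make basin sizes meaningful —
and is why the end-to-end tests assert recovery and energy-rank-1, not
size-rank-1.

## Numerical choices and degenerate inputs

- FFT correlations use real transforms; agreement with the direct
  shift-and-sum is ~1e-15 relative (tested bound 1e-6).
- Alternate locations: highest occupancy wins, ties by file order. Residues
  are ordered by (author number, insertion code).
- Tail trimming calls a terminal residue unstructured if its backbone is
  incomplete or its B-factor exceeds the chain's 90th percentile; runs
  longer than `max_tail` are treated as structure and kept. Trimming
  iterates to a fixed point, which makes it idempotent; `max_tail = 0`
  disables it.
- Empty results are explicit: an empty pose list after docking warns and
  returns empty; a library with zero harvestable fragments raises with the
  full search history attached.
- Problem sizes in the shipped tests and acceptance script (150-fragment
  databases, 12–24 rotations, 8³/16³ oracle grids, 5 000-match stress case)
  were chosen so the full suite exercises every stage, including its
  brute-force oracles, in about a minute on one CPU.
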