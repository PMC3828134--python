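# Methods

This note documents the models and numerical choices behind `bsfp`, the
defaults and their rationale, what the synthetic fixtures do and do not
emulate, and the package's known limitations.

## Structure model and I/O

Structures are held in a light dataclass hierarchy (Atom / Residue /
Structure / Ligand / Trajectory) and read and written as PDB through gemmi.
Author residue numbering and insertion codes are preserved; alternate
conformations keep the highest-occupancy conformer; waters are dropped.
A multi-MODEL file becomes a `Trajectory`; the frame spacing `dt_ps` is
supplied by the caller because PDB carries no time axis.  Hetero groups are
separated into ligands: consecutive hetero residues of nucleic or
amino-acid type in one chain merge into a polymeric ligand; everything else
is a small molecule or, with a single heavy atom, an ion.

A ligand is *legitimate* unless (i) its het code is on the non-specific
list bundled at `data/nonspecific_ligands.txt` (crystallization additives,
buffers, common counter-ions; editable — whether e.g. phosphate or a metal
is genuine is context-dependent), (ii) it is a lone modified amino-acid
residue, or (iii) any of its heavy atoms lies within 1.8 Å of a protein
heavy atom, the covalent-link test that removes glycans and other
covalently attached groups.

Solvent-accessible surface areas use biotite's Shrake–Rupley implementation
with explicit Bondi-type van der Waals radii, a 1.4 Å probe and 300 sphere
points by default (raise `point_number` when sub-percent precision is
needed; rotation invariance holds to <1 % at ~3000 points).  A residue is a
*surface residue* when its SASA reaches 5 % of its residue-type theoretical
maximum — the simplest workable criterion for "surface amino acid
residues", configurable.

Sequence identity is global Needleman–Wunsch (match 1, mismatch 0, linear
gap −1, via Biopython's PairwiseAligner) with identity = identical aligned
positions / alignment length.  Co-optimal alignments can in principle
differ in identity count at equal score; the package reports the aligner's
first optimum.

## Protein graphs and local alignment

Residues are abstracted into typed functional points (donor / acceptor /
mixed / aromatic / aliphatic) at side-chain functional-group centroids.
The typing table is data, not code (`data/functional_points.tsv`); a
residue can emit several points (His: donor + mixed + aromatic), and
unknown residues fall back to an aliphatic side-chain centroid.  Points
within `d_max` form a distance-labelled protein graph.

Pairwise comparison builds the product graph (same-type point pairs;
edges where intra-structure distances agree within `epsilon` and both are
within `d_max`) and extracts its maximum clique with an exact
branch-and-bound solver: vertices are ordered by degree (ties by index) and
a greedy colouring of each candidate set bounds the attainable clique size.
The ordering makes the result deterministic.  The clique seeds a Kabsch
superimposition (scipy `Rotation.align_vectors`; the RMSD is recomputed
from the fitted transform because the solver's reported residual loses
precision near zero).  The correspondence is then extended with mutually
nearest same-type point pairs within `extend_cutoff`, re-superimposed once,
and reduced to residue pairs unique on both sides (closest pairs first).

Defaults: `d_max` 15 Å, `epsilon` 2 Å, `extend_cutoff` 3 Å, `min_clique` 3
— typical local-alignment tolerances; all are carried in `CompareParams`
and echoed in every report.  The hit score is the number of aligned residue
pairs *after* extension, so a near-identical site outranks a minimal seed
match.  Z-scores standardize scores within one search run's hit population
(population sd; fewer than two hits or zero variance give Z = 0).  The
background distribution of the scores is therefore defined by the library
actually searched, which is also why a library with no weak background
matches makes the Z > 0.5 threshold degenerate (see Fixtures).

## Conservation and site prediction

Each homolog is aligned to the query's entire surface.  A residue's raw
conservation is the fraction of successful homolog alignments containing
it; the fraction maps to a degree by `ceil(10·fraction)` clamped to 1–10 —
the simplest rule consistent with a 1–10 scale derived from alignments.
Alignments are unweighted.  Residues at degree ≥ 8 form the predicted site
and are clustered into spatial patches by single-linkage at 8 Å between
residue centroids (connected components of the thresholded distance graph),
reported largest first.  Homolog choice is the caller's responsibility; a
helper flags homologs outside 20–90 % sequence identity as likely too
distant or redundant.

## Ensemble search

The quench schedule is a list of `(t_start, t_end, interval)` segments.
All segments are half-open `[t_start, t_end)`; in a multi-segment schedule
the final segment also includes its endpoint — each boundary time belongs
to the segment that starts there, and the last boundary has no successor.
This is the unique simple convention that yields 20 frames from
`(0, 100, 5)` alone, 10 from the closing `(100, 1000, 100)`, and 30 from
the default two-segment protocol.  Scheduled times must coincide exactly
with trajectory frame times.

Hits from all (frame × library entry) comparisons are pooled and Z-scored
together so frames share one scale; hits at Z ≤ z_min (default 0.5,
strict) are dropped, and one hit per library protein is retained — the
highest Z, ties resolved toward the earlier frame for determinism.

## Annotation

Binding sites are residues with a heavy atom strictly closer than 3 Å to a
ligand heavy atom (hydrogens ignored on both sides; the boundary is
exclusive).  Sites come from the template's own legitimate ligands plus
ligands transposed from homologs with identity strictly above 0.30: the
homolog is superimposed onto the template through a whole-surface local
alignment and the transform is applied to its ligands; duplicates (same het
code, centroids within 2 Å) keep the higher-identity source.  A hit is
retained when the fraction of its matched template residues inside some
site reaches `min_overlap` (default 0.5 — "corresponds with the known
binding site" needs a number; it is configurable and echoed in reports).
Retained hits are classified DNA / RNA / nucleotide / peptide / other from
polymer residue content and an editable het-code table.

## Complex modelling

The receptor site is aligned to the template site; the resulting transform
(template → receptor, so the receptor never moves) carries the template's
ligand into the receptor frame.  Clashes are heavy-atom receptor–ligand
pairs closer than 2.5 Å — a deliberately simple steric score, configurable;
no minimization or flexible placement is attempted.  The written complex
contains the ligand as a separate chain with the transform and clash count
in REMARK records.  Site-based transposition is preferred to whole-backbone
superimposition precisely because, when local site and global fold
disagree, the backbone alignment tends to bury the ligand in the receptor;
the test suite constructs such a case and checks the inequality.

## Trajectory analysis

Hydrogen bonds use donor–acceptor heavy-atom distance ≤ 3.5 Å, plus a
D–H···A angle ≥ 120° whenever an explicit hydrogen sits within 1.25 Å of
the donor; with no hydrogens (the common case for the fixtures) the
criterion is distance-only.  Occupancy is the satisfied fraction of the
analyzed frames; bonds are retained only above the threshold, strictly
(occupancy 0.5 at threshold 0.5 is dropped).  Subset RMSD always follows an
optimal rigid superimposition of the same named-atom selection.

Analysis windows are counted in snapshots backward from the final frame
inclusive: a window of W ns at stride s holds W·1000⁄s snapshots, so the
last 20 ns of a 90 ns, 1 ps trajectory at 1 ps stride is exactly 20,000
snapshots regardless of whether the index starts at 0 or 1.

## Energetics

Single-trajectory MM/GBSA: for each complex snapshot,
ΔX = X(complex) − X(receptor) − X(ligand) with receptor and ligand
coordinates taken from the complex frame, ΔG_bind = ΔE_MM + ΔG_sol, and the
entropy term fixed at zero (the intended use is *relative* affinities of
complexes binding the same ligand in similar poses).  Because coordinates
are shared, bonded (internal) terms cancel exactly; the code asserts this
each frame.  Bonded terms crossing the receptor/ligand partition are
rejected.

Gas-phase terms: harmonic bonds k(r−r₀)² and angles k(θ−θ₀)², cosine
dihedrals k(1+cos(nφ−δ)), Coulomb 332.06·qᵢqⱼ/(ε_int·r) and 12-6
Lennard-Jones with ε_ij = √(εᵢεⱼ), r_min,ij = (r_min,i + r_min,j)/2; 1-2
and 1-3 pairs are excluded and 1-4 pairs scaled by configurable factors
(default 1.0).  No distance cutoff — system sizes here do not need one.

The polar solvation term is a pairwise Generalized Born model: effective
radii from Hawkins–Cramer–Truhlar pairwise descreening (scale factor 0.8,
with the engulfed-atom correction term) and the canonical smoothing
function f_GB = √(r² + BᵢBⱼ·exp(−r²/4BᵢBⱼ)), self term f_GB(i,i)=Bᵢ, so a
single ion reproduces the Born formula exactly.  This is a deliberate,
documented model choice — a molecular-volume GB as implemented inside
dedicated MD packages is out of scope, and published absolute ΔG values
computed with such models are not reproduction targets for this package.
Pairwise descreening is known to overcount overlapping neighbours; a
non-positive inverse radius raises `NumericalDegeneracyError` rather than
silently producing garbage.  The non-polar term is γ·SASA + β with
γ = 0.00542 kcal/mol/Å², β = 0.92 kcal/mol; dielectrics default to 1
(interior) and 78.5 (water); the Coulomb constant is 332.06 kcal·Å/mol/e².

Parameters arrive in a self-contained per-structure sidecar file (globals,
per-atom charge / LJ / GB radius, bonded term lists, TSV sections); force-
field importers are out of scope.  Reported uncertainty is the sample
standard deviation over analyzed frames.

## Synthetic fixtures

The generator builds an expanded helical pseudo-fold: Cα atoms on a helix
(default radius 8 Å, 45° per residue, 2.2 Å rise, per-structure
configurable), backbone stubs along the local tangent, one stub atom per
functional-point typing row placed radially outward, everything spaced so
no two heavy atoms come closer than 2 Å.  A `MotifSpec` plants a rigid
cluster of residues whose primary functional atoms realize a given
geometry exactly (plus optional jitter); ground truth lives in structure
metadata and sidecar JSON, never inferred.  Ligands are planted ~2.7 Å from
motif anchor atoms: inside the strict < 3 Å site rule, outside both the
2.5 Å clash cutoff and the 1.8 Å covalency test.

Two design points deserve emphasis:

* **Decoys carry degraded motif fragments.**  In `make_decoy_db`, decoys
  embed a heavily jittered (0.8 Å) 3-residue fragment of the motif.  A
  library with *no* background similarity would give every pooled hit the
  same score, a zero standard deviation, and an empty result under the
  strict Z > 0.5 rule; real template libraries always present a broad weak
  background, and that background is what Z-standardization measures full
  matches against.  The fragments emulate it at desk scale.
* **Variable periphery needs varied folds.**  For conserved-core
  fixtures, homolog structures are built with different helix parameters
  (`random_helix_params`); with a fixed layout the peripheries would be
  trivially superimposable and spuriously "conserved".

What the fixtures do **not** emulate: real side-chain geometry and packing,
sequence statistics, conformational sampling (trajectory frames are
Gaussian noise around one conformation), solvent, or the size and
redundancy structure of a real template library.  Passing tests therefore
demonstrate the correctness of the algorithms and bookkeeping — recovery of
planted signal under controlled noise — not predictive performance on real
proteins.  One known artefact of the thread-like pseudo-fold: consecutive
functional points span ~7 Å, so a short plain helix may contain no three
mutually-within-d_max points and then yields no seed clique; motif-bearing
fixtures do not have this problem, and globular real proteins are far more
compact than the fixture fold.

## Determinism and degenerate inputs

All randomness is seeded (`numpy.random.default_rng`); clique tie-breaking,
frame tie-breaking and report serialization are deterministic, and the full
pipeline is byte-reproducible under a fixed configuration.  Degenerate
inputs have explicit behaviours: empty regions, missing chains, collinear
superimpositions (< 3 pairs or rank < 2), schedules outside the trajectory,
windows longer than the trajectory, mismatched RMSD selections, overlapping
energetics selections and non-positive GB radii each raise a dedicated
exception naming the offender.

## Limitations

* The comparison engine re-implements the graph/clique approach from its
  published description; it is not output-compatible with any external
  binding-site comparison program, and the Z-score calibration is
  run-internal rather than against a fixed background library.
* Absolute MM/GBSA values depend strongly on the GB variant and radii;
  only closed forms and internal consistency are validated here.
* mmCIF, assemblies/symmetry expansion and hydrogen placement are not
  supported; structures are used as given.
* The exact maximum-clique search is worst-case exponential; it is fast on
  product graphs of realistic sparsity but has no polynomial guarantee.
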