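# bsfp — binding-site comparison and function prediction

`bsfp` is a structural-bioinformatics toolkit for proposing the function of
proteins that cannot be annotated by sequence or fold homology.  The working
hypothesis is that *binding sites* are more evolutionarily conserved, and
more directly tied to function, than whole folds: if an uncharacterized
protein carries a surface patch whose residues match — in physicochemical
type and 3-D geometry — a known binding site in an unrelated protein, that
match is evidence for a shared function.  The toolkit is aimed at
computational structural biologists who want to run or study this workflow
end to end on ordinary PDB files.

## What it does

1. **Conservation mapping** — each residue of a query structure receives a
   structural-conservation degree (1–10) from local structural alignments
   with homologous structures; residues at degree ≥ 8 are clustered into
   candidate binding-site patches.
2. **Ensemble site search** — snapshots are quenched from a molecular-
   dynamics trajectory of the query (default protocol: every 5 ps over the
   first 100 ps, then every 100 ps to 1 ns — 30 frames) and the predicted
   site of every frame is compared against a library of template
   structures.  Hits are Z-scored within the pooled run, thresholded at
   Z > 0.5, and deduplicated keeping the best hit per template.
3. **Annotation** — a hit counts as functional evidence only if the matched
   substructure coincides with a known binding site, defined as the
   residues strictly within 3 Å of a ligand — either co-crystallized or
   transposed onto the template from its > 30 %-identical homologs.
4. **Complex modelling** — a receptor–ligand complex is built by
   superimposing the matched binding sites (the receptor never moves) and
   copying the template's ligand coordinates; steric quality is the count
   of heavy-atom pairs closer than 2.5 Å.
5. **Trajectory scoring** — hydrogen-bond inventories with occupancies
   (retained when occupancy > 0.5), subset RMSDs, and single-trajectory
   MM/GBSA binding free energies over the trailing analysis window.

## The comparison engine

A (sub)structure is reduced to typed *functional points* — pseudoatoms at
side-chain functional-group centroids, typed donor / acceptor / mixed /
aromatic / aliphatic (editable table in `src/bsfp/data/functional_points.tsv`).
Points within d_max = 15 Å are joined into a distance-labelled *protein
graph*.  Two graphs are compared on their *product graph*: vertices are
same-type point pairs (i, j); an edge joins (i, j) and (k, l) when

    |d_query(i, k) − d_target(j, l)| ≤ ε        (ε = 2 Å)

and both distances are within d_max.  A maximum clique of the product graph
— found by an exact branch-and-bound search with a greedy-colouring bound —
is the largest geometrically consistent correspondence.  Its point pairs
seed a least-squares rigid superimposition (Kabsch), after which the
correspondence is extended with mutually nearest compatible pairs within
3 Å; the hit score is the number of aligned residue pairs, standardized to
a Z-score within each search run.

The MM/GBSA estimator follows

    ΔG_bind = ΔE_MM + ΔG_sol − TΔS,   ΔE_MM = ΔE_int + ΔE_elec + ΔE_vdw,
    ΔG_sol = ΔG_GB + ΔG_SA

with the entropy term neglected, a pairwise Generalized Born model
(Hawkins–Cramer–Truhlar descreening radii, canonical f_GB), and
ΔG_SA = γ·SASA + β.  In the single-trajectory scheme the receptor and
ligand coordinates come from the complex snapshots, so ΔE_int cancels
exactly (asserted at run time).

## Worked example

Everything below runs on synthetic fixtures generated by the package — no
downloads.  Build a query carrying a 6-residue motif (residues 25–30), a
3-frame trajectory of it, and a 20-entry library in which 3 "carrier"
structures embed a rotated copy of the motif plus a planted ligand:

```bash
bsfp fixtures toy-protein --n-res 30 --seed 11 --with-motif --out query.pdb
bsfp fixtures toy-traj --base query.pdb --n-frames 3 --noise 0.05 --seed 12 --out traj.pdb
bsfp fixtures decoy-db --n-total 20 --n-carriers 3 --seed 13 --jitter 0.25 --out-dir db

bsfp ensemble-search --traj traj.pdb --dt 1 --schedule "0:3:1" \
     --region "A:25,A:26,A:27,A:28,A:29,A:30" --db db --json-out hits.json
```

```
target_id   score  z_score  rmsd    frame  correspondence
carrier_00  6      2.3094   0.4087  0      A:25~A:35,A:26~A:36,...
carrier_01  6      2.3094   0.3754  0      A:25~A:35,A:26~A:36,...
carrier_02  6      2.3094   0.3592  0      ...
```

All three carriers are recovered with the full 6-residue correspondence
(score 6) at Z ≈ 2.3; the decoys' weak background matches (score ≈ 3) fall
below the Z > 0.5 threshold and are not retained.  The rmsd column is the
residual of the site superimposition under the 0.25 Å planted jitter plus
frame noise.  Filtering against ligand-defined binding sites keeps only the
carriers — the only library entries with a ligand:

```bash
bsfp annotate --hits hits.json --db db
```

```
rank  target_id   ligand_class  overlap  z_score
1     carrier_00  other         0.667    2.3094
2     carrier_01  other         0.667    2.3094
3     carrier_02  other         0.667    2.3094
```

`overlap` is the fraction of each hit's matched residues inside the
template's binding site (4 of the 6 motif residues anchor the planted
ligand, hence 0.667).  `bsfp run --config run.cfg` chains the whole
workflow (conserve → quench → search → annotate → build-model) into one
report directory; see `bsfp run --help`.

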