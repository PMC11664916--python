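# catalocavity

Cavity-based discovery funnel for flavin-dependent photodecarboxylases
(FAPs) and related flavoenzymes.

FAPs convert fatty acids into alka(e)nes and CO₂ using blue light as the
only reagent, which makes new family members attractive for drop-in
biofuel and cascade biocatalysis. Because catalytic ability tracks the
*shape and chemistry of the active site* more closely than sequence,
candidates can be found by comparing binding-site cavities: the cavity
around the flavin and the bound fatty acid is abstracted into an annotated
point cloud ("catalophore") and matched against the cavities of candidate
structures. This package implements that desk-side funnel end to end:

1. **structure_io** — PDB reading/writing, flavin (isoalloxazine) frame
   detection, truncation of long fatty-acid ligands to octanoic acid (C8)
   so the template cavity emphasises the carboxylate-binding region;
2. **cavity** — grid-based cavity point clouds annotated with
   electrostatic potential, H-bond donor/acceptor scores, hydrophobicity
   and buriedness;
3. **matching** — flavin-frame-initialised ICP alignment, bidirectional
   overlap percentages, a [0, 1] total score (lower = better), the funnel
   filters (score < 0.05, overlaps > 70 % / > 10 % or 30 %), and two
   automated triage checks (cofactor on the same side of the cloud;
   potential near flavin N5 stabilising negative charge);
4. **seqpipe** — BLAST-hit filtering (identity ≥ 30 %, bidirectional
   coverage ≥ 80 %), greedy identity clustering at 70 %, and filtering of
   representatives by a reference-equivalent arginine (CvFAP R451, with
   C432/Y466 conservation reporting);
5. **docking_eval** — per-ligand minimal-distance cluster selection,
   combined score |E/d| (binding energy over carboxyl-C-to-N5 distance),
   candidate × ligand score matrices, per-group top-k shortlists;
6. **synthetic_data** — seeded generators for every input (toy tunnel
   enzymes with an FAD mimic and bound fatty acid, cloud pairs with known
   transforms, BLAST tables, sequence families, docking tables) with
   planted ground truth, so the whole funnel runs without databases,
   servers or a docking engine;
7. **pipeline** — one-config orchestration with a deterministic run
   report.

The core statistics, in the field's notation: a match between template
cavity 1 and target cavity 2 is kept iff

    total_score < 0.05,  overlap(1→2) > 70 %,  overlap(2→1) > 10 %
    (30 % for candidate pools larger than 100 structures)

and docking poses are ranked by the combined score |E/d| (E in kcal·mol⁻¹,
d = distance carboxyl C → flavin N5 in Å), summed over the ligand set per
candidate, top-5 per search arm.

## Worked example

Generate a fully synthetic discovery campaign (one template, two targets
that are rigid copies of the template scene, two tunnel-geometry decoys, a
BLAST table over six sequence families, and a docking table) and run the
funnel:

```sh
catalocavity simulate --stage bundle --seed 3 --out bundle
catalocavity run --config bundle/run.yml
```

prints

```
catalocavity 0.1.0 run report

[cavity] templates=1, targets=4, template_points=1253, target_points=4219
[matching] pairs=4, kept_pairs=2, candidates=2
[sequence] hits=24, hits_pass=16, sequences=16, clusters=4, arg_kept=3
[docking] clusters=179, pool=5, shortlist=4

shortlist: fam0_m00 (sequence, sum=15.425), fam1_m00 (sequence, sum=13.677), target_good1 (structure, sum=14.223), target_good0 (structure, sum=10.461)
```

Reading the funnel top to bottom: the template cavity (1253 points around
the C8-truncated ligand) matches 2 of the 4 targets — exactly the two
rigid copies; the decoys fail the score/overlap gates. Of 24 BLAST hits,
16 pass the 30/80/80 filter, collapse into 4 clusters at 70 % identity,
and 3 representatives keep the reference arginine. The pooled 5 candidates
are ranked by their |E/d| sums and the per-group top-2 form the shortlist.
Every number above is predicted by the bundle's manifest
(`bundle/manifest.json`), and `bundle/run/report.json` is byte-identical
across re-runs.

Individual stages are available as `catalocavity prep / cavity / match /
seqfilter / cluster / conserve / dockeval` on ordinary PDB/FASTA/TSV
files; the same functionality is importable (`from catalocavity import
procreate_cavity, align_clouds, filter_hits, build_matrix, ...`).

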