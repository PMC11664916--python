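# Methods

`catalocavity` implements the desk-side stages of a cavity-based enzyme
discovery funnel for flavin-dependent photodecarboxylases (FAPs):
active-site point-cloud ("catalophore") procreation and matching, a
BLAST-derived sequence funnel, docking-score ranking, and an orchestrated
end-to-end run. This note records the model behind each stage, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Cavity model

A binding cavity is represented as a cloud of virtual points filling the
empty space around the protein-bound carboxylic-acid ligand, each carrying
a five-component property vector. Commercial cavity-comparison platforms
do not publish their point placement or property definitions, so the
definitions here are this package's own construction with the same intent:
geometry plus electrostatics, hydrogen bonding, hydrophobicity and burial.
Results are comparable *within* this package, not against any external
scoring scale — except that the score is calibrated so the funnel
thresholds keep their meaning (see below).

**Ligand truncation.** Template structures carry a long fatty acid
(e.g. stearic acid). Cavities computed around the full chain
over-represent the apolar tunnel, so the ligand is trimmed to a fixed
carbon count (default 8, octanoic acid) before cavity procreation:
carboxylate oxygens and the first `keep_carbons` chain carbons are kept,
later atoms deleted, coordinates untouched. Truncation is idempotent and
never moves protein atoms; no energy minimisation is performed (if
minimised coordinates are wanted, minimise externally and feed the result
in as an ordinary structure).

**Flavin frame.** The isoalloxazine plane is fitted by least squares
through {N5, N10, C4A, C5A, C9A, C10} (minimum four present). The frame is
(N5 position, ring centroid, unit ring normal). The normal's sign points
toward the ligand carboxyl carbon when a ligand is given; otherwise it
follows the ordered-atom convention (N10−N5) × (C4A−N5), which is
equivariant under proper rotations. A ligand carboxyl lying exactly in the
ring plane falls back to the atom-order convention. Orthonormal frame axes
are: e3 = ring normal, e1 = in-plane direction centroid→N5, e2 = e3 × e1.

**Point placement.** A regular grid (default spacing 0.8 Å, valid range
0.3–2.0 Å) is laid out **along the frame axes** over the ligand's bounding
box padded by `max_ligand_distance` (default 5.0 Å — small clouds that
emphasise the carboxylate-binding region). Anchoring the grid to the frame
rather than to world axes is what makes procreation equivariant: moving
the structure rigidly moves the cloud point-for-point. A grid point
survives iff

1. its distance to every protein heavy atom is at least that atom's van
   der Waals radius plus 0.5 × probe radius (probe 1.4 Å, Bondi-style
   radii fixed in code: C 1.70, N 1.55, O 1.52, S/P 1.80 Å …);
2. it lies within `max_ligand_distance` of a retained ligand heavy atom
   (ligand and cofactor atoms are treated as empty space);
3. its buriedness is at least `buriedness_min` (default 0.4), excluding
   bulk-solvent points.

Hydrogens are ignored throughout (most crystal structures lack them).

**Properties.**

- *Electrostatic potential*: Σ q/(ε(r)·r) over residue-template integer
  charges within 12 Å, with the distance-dependent dielectric ε(r) = 4r
  (hence q/4r²). Charges: Arg +1 at the guanidinium N centroid, Lys +1 at
  NZ, Asp/Glu −1 at the carboxylate O midpoint; His neutral, termini
  ignored. Parameter-free and sign-correct, which is all the downstream
  filters use.
- *H-bond donor / acceptor*: max over donor (acceptor) protein atoms of a
  linear ramp 1→0 between 2.5 and 4.0 Å. Donor/acceptor atom sets are
  fixed residue/atom-name tables (backbone N donates, backbone O accepts,
  plus the usual side-chain sites).
- *Hydrophobicity*: fraction of protein heavy atoms within 4.5 Å that are
  apolar carbons (element C, excluding backbone carbonyl and
  carboxylate/amide/guanidinium carbons).
- *Buriedness*: fraction of 42 rays (icosahedron vertices + edge
  midpoints) hitting a protein atom within 8 Å. The ray set is expressed
  in the flavin frame; a world-fixed ray set would make buriedness — and
  through filter 3 the point set itself — depend on the structure's
  orientation.

**Degenerate inputs.** Zero surviving points raise `EmptyCavityError`;
empty neighbourhoods during annotation yield zeros; a flavin whose ring
atoms are collinear is rejected.

## Cloud matching and triage

**Alignment.** Every relevant cavity contains a flavin, so alignment is
initialised by superposing the flavin frames (N5→N5, normal→normal,
in-plane axis→in-plane axis) — this builds in the requirement that matches
be consistent with the isoalloxazine orientation — and refined by ICP:
nearest-neighbour pairs within 2ε, Kabsch least-squares update, at most 50
iterations or score improvement < 1e-6, returning the best-scoring
transform seen. If no pair lies within 2ε after frame superposition the
result is the worst case (overlaps 0, score 1), not an error.

**Overlap.** The directional overlap a→b is the percentage of a-points
with at least one b-point within ε = 1.0 Å (grid-spacing scale) that is
*property-compatible*: same electrostatic sign — values inside a dead-band
of 10 % of the cloud's maximum |potential| are wildcards — and donor and
acceptor scores within 0.5. A geometry-only switch is exposed because it
is genuinely unknown whether such platforms count property compatibility
in their overlap.

**Total score.** No published formula exists for the total-score statistic
the funnel thresholds refer to, so the package defines a [0, 1]
dissimilarity preserving its ordering semantics (lower = better,
self-match = 0, disjoint = 1):

    score = 0.7 · (1 − H/100) + 0.3 · P

where H is the harmonic mean of the two directional overlaps (0 if either
is 0) and P is the mean normalised property distance over matched pairs in
both directions (potential differences normalised by 2·max|potential|,
bounded properties by their absolute difference; no matched pairs → P = 1).
The absolute threshold 0.05 therefore selects near-congruent,
property-consistent cavities under *this* score; it is not numerically
interchangeable with any proprietary score.

**Filtering.** A match is kept iff score < 0.05 AND template→target
overlap > 70 % AND target→template overlap > 10 % (> 30 % when the target
pool holds more than 100 structures — the "larger pool" trigger is not
quantified anywhere and is config-exposed). All inequalities are strict;
boundary values fail. Filtering happens first; triage flags are annotated
afterwards and never remove a candidate — they replace the visual
inspection of matching scenes with two automated checks:

- *flavin side*: after mapping the template into the target's space, the
  ring normals must subtend < 90° and both N5 atoms must fall on the same
  side of the plane through the mapped template-cloud centroid normal to
  the ring normal (catches scenes where the clouds superpose but the
  cofactors face opposite directions);
- *electrostatic stabilization*: the mean potential over cloud points
  within 4 Å of N5 must be strictly positive (stabilising toward the
  carboxylate/anion intermediate). No points within 4 Å is reported as
  `None` (inconclusive), deliberately distinct from `False`.

## Sequence funnel

- **Hit filter**: identity ≥ 30 % and *bidirectional* coverage ≥ 80 % —
  read strictly as both query and subject coverage (the looser
  query-only reading is available via the thresholds). Missing coverage
  columns are derived from aligned spans and qlen/slen.
- **Identity**: Needleman–Wunsch global alignment (BLOSUM62, gap open 11 /
  extend 1, via Biopython's PairwiseAligner); identity = 100 × matching
  columns / all alignment columns (gapped columns in the denominator;
  'X' never matches). The pair is aligned in a canonical order so identity
  is exactly symmetric regardless of DP tie-breaks. The alternative
  denominator min(len a, len b) is config-level trivial to add but the
  column-count definition is the one used everywhere here.
- **Clustering**: greedy set-cover (CD-HIT-style) at 70 % identity:
  sequences sorted by length descending (ties by id), the longest
  unassigned becomes representative and recruits everything ≥ cutoff.
  This stands in for cascaded MMseqs2 clustering with the same cutoff
  semantics, deterministically and without an external binary.
- **Conserved-arginine filter**: each representative is globally aligned
  to the reference; the alignment column holding reference position 451
  (1-based) must contain exactly R — a gap or any other residue (e.g. the
  lysine found at equivalent positions in some related enzymes) fails.
  The report also records the columns equivalent to the other two
  conserved-triad positions (432, 466). Position mapping uses the single
  pairwise alignment, no profile: adequate because the conserved positions
  sit in well-conserved blocks, and exactly what the synthetic families
  emulate.

## Docking evaluation

Docking engines are out of scope; their cluster tables are inputs
(candidate, ligand, cluster id, energy E in kcal/mol, distance d in Å from
the substrate carboxyl carbon to flavin N5). Per candidate–ligand pair the
cluster with **minimal distance** is selected (tie → lower energy → lower
cluster id); its combined score is |E/d|, which favours tight and
catalytically close poses. A softer "minimal distance *and* low energy"
reading exists; the minimal-distance rule is the operational one, and a
Pareto report of (d, E)-non-dominated clusters is exposed for reviewers.
Missing pairs score 0 rather than being dropped, keeping row sums
comparable across candidates with unequal docking coverage. Candidates
are ranked by row sum; the shortlist takes the top k (default 5) per
provenance group, mirroring a per-source selection such as 5 + 5 finalists
from a sequence arm and a structure arm.

## Pipeline

`run_all` executes: templates → truncated-ligand clouds; targets → clouds;
all template × target matches, filtered, **union over templates** (several
related templates are used precisely to widen the net, so any-pass
admits); BLAST filter → clustering → arginine filter, whose surviving
representatives join the candidate pool directly (homology modelling is
external — structures derived from sequence candidates can simply be added
as targets); docking evaluation over the pool with provenance groups;
per-group top-k shortlist. Reports (JSON + text) carry per-stage counts,
triage flags and the config echo, no timestamps: re-runs with the same
config are byte-identical.

## Synthetic data

Generators emulate every input with planted ground truth; all randomness
flows through one seeded NumPy generator per call, and manifest
expectations are computed by plain brute-force enumeration, independent of
the production code paths they later check.

- *Toy enzyme*: a cylindrical shell of ~290 apolar carbon pseudo-residues
  (radius 6 Å, length ~17 Å, capped head, jittered by σ = 0.08 Å so no
  atom sits on an exact grid/ray coincidence), a linear C8–C18 fatty acid
  on the axis, a planar six-atom isoalloxazine mimic at the tunnel head
  with N5 nearest the carboxyl carbon, and optionally an arginine-like +1
  or aspartate-like −1 side-chain mimic ~3.5 Å from N5. Scenes can be
  emitted in any rigid pose. Typical size ~300 atoms, cavity ~1200 points
  at default parameters.
- *Cloud pairs*: cloud B is a known rigid transform of a subset of A plus
  decoys kept ≥ 2ε from every mapped point, so both directional overlaps
  are exact by construction.
- *BLAST tables*: 16-column (outfmt-6 + qlen/slen/qcovs/scovs) rows with a
  planted number of passes; failing rows miss a threshold by a clear
  margin, never at the boundary.
- *Sequence families*: same-length sequences sharing a conserved scaffold
  (every 7th position plus a block spanning the triad) copied from a
  generated reference; members are point mutants of their family seed at
  non-scaffold positions (≤ 5 % each, so within-family pairwise identity
  ≥ 90 % while between-family identity stays ≈ 25–35 %). Equal lengths
  and the scaffold make the optimal global alignment gapless, so the
  reference position maps to the same column in every sequence — which is
  what isolates the residue-filter test from alignment noise.
- *Docking tables*: 1–4 clusters per pair, energies U(−12, −1) kcal/mol,
  distances U(2.5, 9) Å, a small fraction of pairs left undocked; the
  manifest enumerates the expected matrix, sums and per-group top-k.
- *Funnel bundle*: composes all of the above into one directory with a
  run-config whose outcome is fully predicted (two rigid-copy targets must
  match, two tunnel-geometry decoys must not; four of six sequence
  families pass the BLAST filter and three keep the arginine; the
  shortlist is the per-group top-2 of the five pooled candidates).

**What passing tests show — and don't.** The toys establish that the
geometry engine, filters, alignment, funnel logic and ranking are
implemented correctly and deterministically. They do not establish
discovery performance on real proteins: real cavities are irregular, real
charge distributions are not single planted side chains, real sequence
families have indels and domain architecture, and real docking energies
are correlated with geometry. Threshold values (0.05 / 70 / 10 / 30 / 70 /
451) are the funnel's operating points, not quantities validated by the
synthetic data.

## Problem sizes and numerical notes

Tests and the acceptance script run toy enzymes of ≤ 500 atoms (~1–2 × 10³
cavity points), 200-point cloud pairs, 5 × 10-member sequence families plus
20 single-member families, and 14 × 25 docking tables — sizes chosen so
every check runs from scratch in seconds while still exercising all code
paths at realistic funnel shape. Further notes:

- Overlap percentages are computed as 100·count/n (integer count), so
  oracle comparisons are exact, not approximate.
- Matrix row sums use per-row 1-D summation so independently recomputed
  sums agree bitwise; permuting the ligand axis changes sums only at
  floating-point associativity level (≲ 1e-15 relative).
- ICP nearest-neighbour ties resolve deterministically through the KD-tree
  query; the frame initialisation makes the refinement deterministic in
  practice.
- The 42-ray buriedness is a coarse estimator; with the frame-anchored ray
  set it is exactly equivariant, but grazing rays make it sensitive to
  sub-Å atom displacements — acceptable because it only gates points near
  the 0.4 threshold.

## Known limitations

- Electrostatics are Coulomb-with-screening, not Poisson–Boltzmann; His is
  neutral; protonation states and termini are ignored.
- No conformational sampling: one structure, one cloud.
- Rigid alignment only; no flexible or deformable cavity matching.
- The total-score statistic is a reconstruction; absolute values are not
  comparable with any external platform's scores.
- PDB input only (no mmCIF); altloc handling keeps the highest-occupancy
  conformer.
- The sequence funnel does not run BLAST/MMseqs2 and performs no
  profile/HMM mapping; external-database properties of a real search
  (hit caps, identity decay deep in the hit list) are out of reach.
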