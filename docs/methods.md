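# Methods

This note records the scientific and numerical choices behind `epimimic`:
what is computed, which parameters matter, what the synthetic benchmark
does and does not emulate, and where the design space was genuinely open.

## Surface model

**Accessibility.** Per-residue solvent accessibility is the Shrake–Rupley
accessible surface area (biotite implementation, probe 1.4 Å, 1000 sphere
points, element-based van der Waals radii C 1.70 / N 1.55 / O 1.52 /
S 1.80 Å), divided by the residue's theoretical maximum in an extended
Gly-X-Gly context (Tien et al. 2013 values) and clipped to [0, 1]. A
residue is *accessible* when its relative SASA reaches a threshold,
default **0.05**. The threshold is deliberately permissive: buried epitope
residues are rare, and a stricter cut fragments the surface into segments
too short to seed peptides. Both probe radius and threshold are arguments
of `compute_accessibility`.

**Segments.** Maximal runs of chain-contiguous accessible residues
(contiguity = consecutive position in the chain's residue ordering,
insertion codes respected — never sequence-number arithmetic). A segment's
centre of gravity is the unweighted mean over all its heavy atoms (no mass
weighting: the quantity is geometric); its termini are the Cα positions of
the first and last residue.

**Clusters.** Average-linkage hierarchical clustering of segment
centre-of-gravity distances, cut at a height of **20 Å** (configurable).
This is a deliberate functional stand-in for tree-based aggregation of
inter-segment distances: it reproduces the qualitative behaviour that the
cluster count stays roughly flat as antigen size grows (segments and
patches grow instead), and it is deterministic. Whether a tree should be
cut by height or by count is not decidable from first principles; height
was chosen because it keeps cluster spatial extent, not cluster number,
constant.

**Patches.** One patch per segment: all segments whose centre of gravity
lies within the radius (10 or 15 Å) of the reference segment's centre,
boundary inclusive (consistent with the epitope contact rule). Hence
`#patch10 = #patch15 = #segments` identically.

**Varying patches.** One per accessible residue. Accessible-residue counts
are taken at Cα–Cα radii 15–20 Å (1 Å steps) around the reference Cα; the
selected radius is the smallest whose count reaches the mean of the six
counts ("the radius collecting the average number"). Membership counts
accessible residues only, because peptides are built exclusively from
accessible residues. Hence `#varying_patches = #accessible residues`.

## Design methods

All tie-breaks throughout (equal distances, equal scores, equal counts)
are lexicographic on element ids, so every method is deterministic without
seeds; banks are byte-identical across runs.

**Prime family.** NN grows a peptide C-terminally from a reference
segment, repeatedly appending the unused segment nearest (centre-of-gravity
distance) to the most recently appended segment — *chained* growth, chosen
because "the forming peptide" has a moving end; reference-anchored ranking
is available as a configuration of the same routine. A segment that
overshoots the requested length is appended whole, which is why final
lengths exceed requested lengths by a couple of residues on average. uNN
uses NN's selection but joins each segment through whichever terminus is
closer to the forming peptide's C-terminal residue (reversed sense if the
C-terminus is closer; ties keep the natural sense). FN uses NN's selection
order but alternates placement C-terminal / N-terminal so the reference
stays central — selection and placement are decoupled, which makes the
FN segment multiset provably equal to NN's when both take the same number
of segments. ONN / OFN / OPP reorder the NN set, the FN set, or the 10 Å
patch members to the arrangement with the smallest total inter-segment
centre-of-gravity distance; no extra residue is added, segments are
concatenated in natural sense.

**Path optimisation.** Open-path minimisation is exact Held–Karp dynamic
programming up to **12 nodes** and a deterministic nearest-neighbour
construction (every start) followed by 2-opt segment reversals in a fixed
scan order beyond. Undirected solutions are canonicalised against their
reversal. The exact bound covers every optimizer invocation the tests
compare against exhaustive enumeration.

**Linker family.** Between consecutive segments of a prime peptide:

* *ALA* inserts `max(0, round(gap/3.8) − 1)` alanines, where the gap is the
  distance from the carbonyl C of the residue ending the first segment to
  the amide N of the residue starting the next (in peptide orientation)
  and 3.8 Å is the span of one virtual peptide bond. One bond is free (the
  junction itself); each additional bond the gap accommodates buys one
  alanine. The rounding form is a declared stand-in for the prose rule
  "as many times as the distance allows a peptide bond".
* *SA* looks up the protein-block labels of the two junction residues
  (whole chains are PB-encoded once; a residue whose 5-residue window is
  incomplete gets a null label, and junctions involving a null label
  receive no insertion). If the PB transition is allowed, nothing is
  inserted; otherwise the single PB maximising the weaker of the two hop
  weights is inserted, then the best pair; if no bridge exists the peptide
  is flagged impossible and excluded from banks. Inserted PBs contribute
  their preferred amino acid at the central window position.
* *SAS* inserts exactly one residue per junction: the four real residues
  framing the junction are treated as the outer positions of a PB window
  whose centre is the residue to insert, the computable pseudo-dihedrals
  are matched to the 16 prototypes by NaN-tolerant RMSDA, and the winning
  block's preferred central amino acid is inserted (alanine if no window
  geometry exists at all).

**Graph family.** Three graphs, edges weighted by Euclidean distances:
*natural* (directed, segments, C-terminus → N-terminus weights, traversal
only in natural sense), *reversed* (undirected, minimum over the four
terminus pairings; assembled peptides orient each segment to enter through
the terminus nearest the previous exit), and *aa* (undirected, accessible
residues, Cα–Cα). SHP methods take, over all pairs of area elements, the
shortest path covering the most residues (ties: smaller total distance,
then lexicographic); the requested length plays no role, so SHP output
lengths are invariant to it. In the aa graph Euclidean weights satisfy the
triangle inequality, so shortest paths are direct edges except at exact
ties — SHPaa peptides are short by construction, which matches the
method's known weakness. TSP methods order the area elements along the
minimum-distance open path, enumerate every contiguous run that first
reaches the requested length, and pick the run by the variant rule:
1 highest segment-score sum, 2 shortest travelled distance, 3 shortest
distance per segment, 4 containing the area's two closest elements,
aa shortest travelled distance. An area holding fewer residues than
requested yields the whole path, flagged `short`.

**Scoring.** `Ss = Naa + Naccess + Nhyd + Nwryp + Nturn` per segment,
summed over segments for the peptide score. `Naccess` is the mean relative
SASA scaled by **10** so its magnitude is commensurate with residue counts
— this scale is the formula's biggest unknown and is configurable. The
hydrophobic set is {A, C, F, I, L, M, V, W}; W/R/Y/P are counted
independently (a tryptophan increments both terms). Turn residues come
from a Kabsch–Sander hydrogen-bond assignment (amide H inferred from the
preceding carbonyl, electrostatic energy below −0.5 kcal/mol, CO(i)→NH(i+n)
for n = 3, 4, 5 marking residues i..i+n); passing no turn set makes the
term contribute zero for structures without full backbones.

**Banks.** Prime/linker methods design one peptide per segment;
segment-graph methods one per cluster plus one per 15 Å patch; aa-graph
methods one per cluster plus one per varying patch. Within a method,
duplicate sequences are removed (first reference wins) and impossible
peptides are excluded.

## Evaluation

Composition mode uses multiset matching — each epitope residue credits at
most one peptide position — implemented as a counter intersection and
cross-checked in the tests against an independent sorted-merge oracle.
Position-aware mode credits a position only if its source residue key is
an epitope residue (each creditable once); linker positions are compared
last, by identity, against the still-uncredited epitope residues, so a
linker can rescue a missed epitope residue but never double-credit. The
position-aware counts are a sub-matching of the composition matching, so
position-aware Se and PPV never exceed their composition counterparts.
Thresholded summaries use strict inequality on both metrics
simultaneously (default 0.7). When an antigen has several epitopes each
peptide is scored against each independently; summaries take the best.

The chance probability is evaluated in log space via `gammaln`, returning
exactly 0 when the peptide demands more copies of a residue type than the
accessible pool holds. On small pools the probability provably normalises
over all sequences of each length (tested exhaustively).

## Protein-blocks data

The 16 prototype windows (8 dihedrals each) are the canonical published
reference angles of the structural alphabet. The original transition-weight and
amino-acid-propensity statistics were derived from a structure-database
survey; that survey is not reproducible inside this package, so the
shipped tables are **synthetic stand-ins**, clearly
labelled in their filenames and headers: transition weights decay
exponentially with the RMSDA between the 6 dihedrals shared by consecutive
overlapping windows (zero beyond 90°, so ~40 % of transitions are allowed
and every disallowed pair is bridgeable by one insertion), and propensities
score each window position with the classical Chou–Fasman helix / sheet /
turn scales according to the position's prototype (φ, ψ) conformation.
Both files are plain TSV and swappable via `PBLibrary`; all algorithms
over them (encoding, transition queries, bridging, preferred residues) are
exact. The "allowed" threshold defaults to any strictly positive weight.

## Synthetic benchmark

The fixture generator builds ideal-geometry backbones (N, Cα, C, O, Cβ;
Engh–Huber-style bond lengths and angles from a single data file) from
dihedral templates (helix −57/−47, strand −120/130, coil sampled from a
fixed allowed-region pool), with sequences drawn from a seeded RNG over the
18 amino acids that take an ideal Cβ (no Gly/Pro). Accessibility can be
forced by a direct annotation mask or by a physical cage of occluder
points that the SASA computation sees but receives no area from.
Antigen–antibody complexes plant one minimal antibody probe residue per
requested contact, outward along the local surface normal, and the
construction is validated: planted minimum atom distances are exact to
0.01 Å and unplanted residues stay beyond a guard distance. The randomized
benchmark spec plants 3–8 epitope segments of 1–4 residues at contact
distances 3.2–3.95 Å on a 90-residue extended chain, mirroring the
segment-rich composition of crystallographic discontinuous epitopes
(which average ~7 segments of ~2.4 residues).

What this emulates: discontinuity, exact contact geometry, burial
patterns, and every counting identity of the surface model. What it does
not: real side chains and packing (fixtures stop at Cβ), native surface
curvature, antibody paratope structure, and the composition biases of real
epitopes. Passing tests therefore demonstrate algorithmic correctness and
the methods' structural identities (length behaviour, counting rules,
optimality, provenance round-trips), not wet-lab mimicry performance on
crystallographic datasets — benchmark-scale figures on real complex sets
require those structures as input and are produced by the same pipeline
via the CLI.

`scripts/acceptance.py` uses 6 synthetic antigens of 90 residues with a
25 % burial rate (epitope residues kept accessible so mimicry is
attainable), requested lengths 12 (prime/linker) and 16 (graph) — sizes
chosen so the whole run completes in well under a minute while every
method family is exercised at benchmark-like segment counts.

## Known limitations

* The SASA of fixture structures underestimates large side chains (atoms
  stop at Cβ); relative thresholds are calibrated accordingly.
* The reversed-graph segment orientation is resolved greedily along the
  path, not globally; a globally optimal orientation assignment would be a
  2^k search for marginal gain.
* SA/SAS linker choices are only as good as the synthetic PB tables;
  swapping in survey-derived tables changes inserted residues but no
  algorithmic behaviour.
* `deduplicate_complexes` trusts the manifest's complex keys; it does not
  infer antigen identity from coordinates or sequence.
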