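# epimimic

Design of linear peptides that mimic **discontinuous B-cell epitopes** from
the 3D structure of a protein antigen, together with the benchmarking
machinery to measure how well designed peptides match crystallographic
epitopes.

Most antibody epitopes are discontinuous: the residues an antibody touches
are scattered along the antigen sequence but adjacent on the folded
surface. A linear peptide can only mimic such an epitope if the design
walks the antigen surface and decides in which order to stitch the exposed
fragments together. `epimimic` implements that walk 34 different ways and
quantifies the outcome, for people who need surrogate peptides for
immunoassays, epitope mapping or immunogen design.

## The model

The antigen surface is decomposed into **segments** — maximal runs of
chain-contiguous, surface-accessible residues (relative Shrake–Rupley SASA
above a configurable threshold, default 0.05). Segments are grouped into

* **clusters** (average-linkage agglomeration of segment centres of
  gravity, cut at 20 Å),
* **patches** (all segments whose centre of gravity lies within 10 or 15 Å
  of a reference segment's centre), and
* **varying patches** (all accessible residues within an adaptive
  15–20 Å radius of a reference residue, the radius chosen so its residue
  count first reaches the mean count over the six candidate radii).

Three method families then assemble a peptide:

| family | methods | principle |
|---|---|---|
| prime | NN, uNN, FN, ONN, OFN, OPP | greedy concatenation of nearest segments around a reference; the O-variants reorder the collected set to the arrangement with the shortest total inter-segment distance |
| linker | {NN, uNN, ONN, FN, OFN, OPP}ala, {NN, ONN, FN, OFN, OPP}sa, {NN, ONN, FN, OFN, OPP}sas | insert alanines filling the spatial gap (one per peptide bond beyond the first, `max(0, round(gap/3.8) − 1)`), or residues chosen through the 16-letter protein-blocks structural alphabet (allowed-transition bridging for SA, junction superposition for SAS) |
| graph | SHPnat, SHPrev, SHPaa, TSPnat1–4, TSPrev1–4, TSPaa | model segments (directed N→C, or undirected) or single accessible residues as distance-weighted graph nodes over a cluster or patch; cut the peptide from a shortest path (SHP) or an open travelling-salesman path (TSP, exact Held–Karp up to 12 nodes) |

A designed peptide carries per-position provenance (source residue or
linker marker), so it can be evaluated against a crystallographic epitope
(antigen residues with any heavy atom ≤ 4 Å from the antibody) in two
modes:

* **composition** — multiset matching on amino-acid identity:
  `tp = Σ_aa min(count_peptide, count_epitope)`;
* **position-aware** — a position counts only if its *source residue* is an
  epitope residue; linker residues are matched last, by identity, against
  still-uncredited epitope residues.

From the counts, sensitivity `Se = tp/(tp+fn)` (epitope coverage) and
positive predictive value `PPV = tp/(tp+fp)` (peptide purity). Two chance
baselines are provided: random peptides drawn from the antigen composition,
and the closed-form probability of drawing a given sequence without
replacement from the accessible residue pool,
`P = (Π_X A(n_X, p_X)) / A(n, P)` with `A(n, p) = n!/(n−p)!`.

## Worked example

Everything runs on synthetic fixtures — no downloads. Build a toy
antigen–antibody complex with five contacts planted at exact distances,
then design a 12-mer with the TSPaa method from the first cluster:

```
$ epimimic fixtures make --kind complex --n-residues 40 --seed 7 \
      --contacts "5:3.9,6:3.8,12:3.5,13:3.4,20:3.6" --out antigen_ab.pdb
wrote antigen_ab.pdb

$ epimimic design antigen_ab.pdb --chains A --method TSPaa --reference 1 --length 12
{
  "method": "TSPaa",
  "sequence": "TDTDLTHIHRFY",
  "final_length": 12,
  "requested_length": 12,
  "path_distance": 41.84,
  "score": null,
  "status": "ok"
}
```

The peptide is the 12-residue window with the shortest travelled distance
along the optimal path through the cluster's accessible residues:
`final_length` equals the requested length exactly (a TSPaa identity — each
graph node is one residue), and `path_distance` is the Cα–Cα length of the
walk in Å. `epimimic bank` generates whole-surface banks (FASTA + per-position
provenance TSV) for any subset of the 34 methods, and `epimimic evaluate`
scores a bank against the crystallographic epitope of a complex in both
evaluation modes.

The same operations are available as a library:

```python
from epimimic import read_structure, compute_accessibility, build_surface_model
from epimimic.peptide_design import generate_peptide_bank

antigen = compute_accessibility(read_structure("antigen_ab.pdb", chains="A"))
model = build_surface_model(antigen)
bank = generate_peptide_bank(model, "TSPrev2", requested_length=16)
```

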