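# Methods

## Problem and model

Cross-linking mass spectrometry (XL-MS) reports pairs of peptides joined by
a chemical cross-linker, together with the linked residue positions. A
cross-link is *intra* when both peptides come from the same protein sequence
and *inter* otherwise. Two signals hidden in nominally intra links point to
homo-multimers:

1. **Overlapping peptide sequences (OPS).** If the two linked peptides
   overlap on the protein sequence — by even one residue — they cannot both
   come from a single chain (barring internal sequence duplication). The
   extreme case is a self-link, a residue cross-linked to itself.
2. **Out-of-range distances.** If the shortest protein-volume-avoiding path
   between the two linked residues on a known structure exceeds the
   linker's span, a single-chain interpretation is geometrically
   implausible; on a homo-multimeric structure the same link may fit across
   two copies of the protein.

The pipeline normalizes link positions to full-protein coordinates, runs the
OPS analysis, selects structural templates, computes Euclidean and
topological distances over all chain-pair assignments, and classifies every
link into exactly one category (`intra_within_range`, `intra_out_of_range`,
`ops_inter`, `ops_inter_validated`, `out_of_range_inter_validated`,
`inter_within_range`, `inter_out_of_range`, `unmapped`).

## Position mapping

Peptides are aligned to their protein with Smith–Waterman local alignment
(Gotoh affine-gap recurrences). Scoring defaults: match +2, mismatch −1,
gap open −4, gap extend −1, where a gap of length k costs
`gap_open + (k−1)·gap_extend`. These are a simple identity-dominant choice
(peptides are near-exact substrings of their protein in practice) and are
configurable. Traceback ties prefer the diagonal, then the vertical, then
the horizontal move, and among equal-scoring end cells the smallest
(target end, query end) wins, making results fully deterministic.

A link site maps to the protein position aligned with it; the mapping is
rejected when the link column does not align to an identical residue and the
alignment does not cover the whole peptide. When the same peptide has
several equal-scoring placements, the smallest-start placement is used for
position mapping (with a diagnostic), while the OPS analysis instead uses
the placement pair that *minimizes* overlap — the conservative choice that
implements the duplicated-peptide caveat: a peptide duplicated within one
sequence can explain an apparent overlap without any multimer.

Redundancy elimination collapses exact duplicates under the unordered
(protein, position) pair key, keeping the first occurrence and recording
multiplicity. When a row supplies both peptide-level and protein-level
positions and they disagree, the alignment-derived value wins and a
diagnostic is issued.

## Template selection

Each protein is aligned against every chain of every structure in the local
library. A chain qualifies when sequence identity ≥ 0.90 (over alignment
columns, gaps included) and coverage ≥ 0.50 (aligned residues over full
protein length); experimental structures additionally need a recorded
resolution ≤ 4 Å. Candidates rank by identity (desc), coverage (desc),
resolution (asc, absent last), then structure id — a total order, so runs
are repeatable. Predicted models (pLDDT in the B-factor column, read from
the alpha-carbon) are a fallback used only when no experimental structure
qualifies; they are first trimmed to residues with pLDDT ≥ 70 and are exempt
from the resolution cutoff, pLDDT being their quality gate. Complex
templates require passing chains for both query proteins; a homo-multimer
query needs at least two distinct passing chains, and only experimental
structures are searched (a single-chain predicted model carries no
quaternary information). Files without header resolution are treated as
predicted models unless the caller states otherwise; experimental files
without resolution fail the resolution gate.

## Distances

The anchor atom is the beta-carbon (alpha-carbon for glycine or when the
beta-carbon is unobserved; configurable to alpha throughout) — the standard
convention for modelling lysine-reactive linkers. The Euclidean distance is
the straight line between anchors. The topological distance is the shortest
spatial path that avoids the protein volume, computed on a voxel occupancy
grid:

- voxel spacing 1.0 Å (configurable); grid covers the evaluated chains'
  bounding box plus a padding that defaults to the maximum linker length, so
  capped searches never leave the grid;
- a voxel is blocked when its center lies within (element van der Waals
  radius + probe radius 1.4 Å) of any retained atom; waters are dropped at
  parse time (solvent is not an obstacle), other heteroatoms count;
- a clearance sphere of 4 Å around each endpoint is carved free so link
  sites are never sealed in by their own side chains;
- only the chains of the assignment under test occupy the grid, so a
  single-chain evaluation is not obstructed by the rest of the assembly;
- the path is found by A* over the 26-connected free voxels with step costs
  spacing·{1, √2, √3}; the Euclidean center-to-center heuristic is
  consistent (each step costs exactly its Euclidean length), so the result
  equals plain Dijkstra on the same graph — a property the tests pin against
  an independent sparse-graph Dijkstra;
- if the straight anchor–anchor segment crosses no blocked voxel, the
  Euclidean distance is returned directly;
- searches are abandoned beyond a cap (default 2 × linker max); an
  unreachable result is treated as out of range — positive evidence against
  the tested interpretation, not missing data.

The path is any volume-avoiding path, not one forced to hug the protein
surface: an approximation to exact polyhedral shortest paths that is
accurate to about one voxel diagonal. The reported length is between voxel
centers, so `topological ≥ euclidean − spacing·√3` always holds; free-space
values are exact by the straight-line shortcut.

## Classification cascade

1. OPS intra-links are reclassified as inter-links and evaluated cross-chain
   on homo-complex templates; a topological distance within the linker span
   (default 5–35 Å) validates them (`ops_inter_validated`).
2. Other intra-links are evaluated same-chain on the best template. Within
   range → kept intra. Out of range → evaluated cross-chain on homo-complex
   templates; within range validates the remap, otherwise
   `intra_out_of_range`.
3. Inter-links are evaluated cross-chain on shared complex templates.
4. Links with no usable evaluation anywhere are `unmapped` (their OPS flag
   is still reported).

Across the enumerated chain permutations the verdict uses the minimum
finite topological distance (ties: smaller Euclidean, then lexicographic
chain pair); all per-assignment results are retained in the output. By
default only the top-ranked template is evaluated (`candidate_depth`
configurable).

## Synthetic data

The fixture generator builds ideal helices (rise 1.5 Å, twist 100°, radius
2.3 Å, giving the canonical ~3.8 Å consecutive-CA spacing) with N/CA/C/O/CB
backbones, random 20-letter sequences whose k-mer windows are unique (so
every fixture peptide has a single optimal placement), and writes standard
FASTA/CSV/PDB files plus a truth manifest. Scenarios:

- **homodimer** — two antiparallel 60-residue helices 14 Å apart; one link
  fits within a chain, one only fits across the interface (same-chain span
  ~77 Å, cross-chain ~11 Å). A monomer-only variant shows the same link
  degrading to `intra_out_of_range`.
- **ops** — intra-links whose peptides overlap by exactly 0, 1, 5, and 10
  residues, plus a self-link; no structures.
- **predicted_model** — a 50-residue model with pLDDT 55 on residues 1–15
  and 90 elsewhere; a link anchored in the low-confidence segment becomes
  unmappable at the default cutoff.

Scenario sizes (40–60 residue helices) keep occupancy grids near 10⁶ voxels
and the full test suite in tens of seconds. What the fixtures do **not**
emulate: real side-chain packing and cavities, disordered regions,
crystallographic artifacts (alternate conformers beyond a toy case,
insertion codes), sequence–structure mismatches from isoforms, and search
engine noise in peptide identification. Passing the fixture suite therefore
demonstrates the correctness of the mapping, overlap, selection, distance,
and classification logic — not field performance on any particular
experimental dataset.

## Numerical and degenerate-input choices

- Alignment and ranking tie-breaks are fully specified (see above);
  repeated runs are byte-identical.
- An alignment with no positive-scoring cell is the empty alignment
  (score 0, no intervals).
- Empty cross-link tables and empty libraries are valid inputs producing
  empty outputs, not errors; malformed rows become per-row diagnostics and
  never abort a run.
- Alternate locations resolve to highest occupancy, then first seen;
  multi-model files use model 1 only.
- Grid path lengths are floating-point sums of identical step costs in
  deterministic order; oracle comparisons use 1e-9 tolerances.

## Known limitations

- The occupancy-grid path is a voxel approximation; distances carry an
  error up to about one voxel diagonal and depend mildly on grid alignment.
- Quaternary structure is taken from the coordinate file as deposited; the
  pipeline does not distinguish biological from crystallographic assemblies
  or infer stoichiometry.
- Isoform and sequence-version mismatches between the FASTA and a structure
  are handled only through the identity/coverage gates.
- Remote retrieval (sequences, structures, predicted models) is out of
  scope; the analysis core operates on local files only.
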