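# Methods

## Problem and model

An enzyme family's reaction and substrate specificity is largely decided by
the residues lining its ligand-binding pocket. The package models each
family member as a fixed-length *active-site string*: one symbol (20
residues, `X` unknown, `-` deleted) per reference pocket position. Members
are grouped by chemical equivalence of these strings — the working
assumption being that members whose pocket residues share physicochemical
character are likely isofunctional, and that positions whose chemistry
differs systematically between groups are candidate
specificity-determining positions.

The pipeline has four stages — pocket definition, site extraction, pairwise
scoring, density clustering — plus summaries. External heavy machinery
(homology modeling, machine-learned pocket scoring, structural
superposition) is deliberately out of scope: the package parses the
standard outputs of those tools (PDB files, P2RANK predictions CSV,
aligned-FASTA pairs) rather than re-implementing them.

## Pocket definition

A pocket is an ordered list of author-numbered residue positions
`(chain, number, insertion code)` on one reference structure, always sorted
ascending so downstream site strings are position-comparable across runs
and sources. Sources:

* **P2RANK CSV** — parsed with case-insensitive, whitespace-tolerant
  headers (`name`, `score`, `residue_ids`); the highest-score pocket is
  selected by default, a `--pocket-rank` flag picks another; score ties
  keep file order for determinism.
* **Ligand proximity** — every polymer residue with a heavy atom within
  `cutoff` (default 4.5 Å, the conventional first-contact-shell distance)
  of a heavy atom of the ligand; the largest HET component is used when no
  ligand name is given; water is always excluded. This is a geometric
  substitute for a learned pocket scorer, adequate when a holo reference is
  available.
* **User list** — `chain_number[icode]` tokens, deduplicated and ordered.

## Site extraction

Pocket positions are first resolved to 0-based indices in the reference
polymer sequence (via the structure's residue order when a structure is
given; otherwise residue numbers are read as 1-based sequence positions).
Each index is then located in the gapped reference row of an alignment, and
the aligned row's character at that column becomes the member's site symbol
(`-` where the member is gapped). The 3D route uses one pairwise alignment
per member (reference row first); the 2D route uses the MSA row of the
reference for the column mapping and reads every other row at those
columns. When the pairwise alignments are exactly the MSA's induced pairs,
the two routes are character-identical by construction — a property the
test suite enforces and `compare_2d_3d` quantifies on real data.

Two filters guard the mapping:

* **Identity gate** — percent identity is matches over both-non-gap
  columns (insensitive to terminal-gap padding conventions; the denominator
  choice is ours). The threshold is ≥ 30 % inclusive, adjustable. With
  several references, each member keeps the best-identity reference (ties:
  input order); pockets of co-references must have equal length.
* **Gap discard** — sites with gap fraction strictly above 0.5 (adjustable)
  are dropped; every discard is logged with member id and reason.

A fallback global aligner (Needleman–Wunsch semantics via
`Bio.Align.PairwiseAligner`; BLOSUM62, affine gaps, open 10 / extend 0.5
subtracted, gap of length ℓ costing `open + (ℓ−1)·extend`, end gaps
penalized) serves only when a model has no supplied alignment. Its scores
are verified against exhaustive alignment-space enumeration; the trace-back
is the aligner's deterministic canonical first alignment.

## Residue distance matrix and score matrix

The default matrix partitions the residues into six classes — aliphatic
{A,V,L,I,M}, aromatic {F,W,Y}, polar {S,T,N,Q,C}, basic {K,R,H}, acidic
{D,E}, conformationally special {G,P} — with d = 0 on the diagonal, 0.3
within a class, 1.0 across classes, 1.0 residue-vs-gap, d(-,-) = 0, and
X at 0.5 from everything but itself (unknowns mildly penalized, never
treated as matches or gaps). The matrix is symmetric, [0, 1], and satisfies
the triangle inequality (verified exhaustively over all symbol triples).
The 0 / 0.3 / 1.0 levels are this package's own calibration of
"same residue / same chemistry / different chemistry"; any alternative
matrix over the same alphabet can be loaded from a labeled TSV and is
validated against every invariant on load.

The distance between two sites is the arithmetic mean of per-position
entries. Because entries lie in [0, 1], the all-vs-all score matrix lies in
[0, 1] by construction with no separate rescaling pass, has a zero diagonal
and is exactly symmetrized against float noise. No position weighting is
applied.

## Clustering

DBSCAN runs directly on the precomputed score matrix: a point is core when
≥ `min_samples` points (itself included) lie within `eps`; clusters are
eps-connected components of core points plus their border points. Border
points reachable from several clusters go to the cluster formed first under
index-order expansion — classic DBSCAN leaves this unspecified, and the
deterministic rule makes runs reproducible and oracle-testable. Noise is
reported as label 0 and listed in an explicit unclustered section, so every
input member is always accounted for; clusters are renumbered 1..K by
decreasing size (ties: smallest member index).

**Automatic parameters.** `min_samples = max(5, round(ln n))` — a slowly
growing density requirement with a floor that keeps tiny spurious clumps
from qualifying as dense. For eps, every distinct value of the k-distance
curve (each point's distance to its min_samples-th nearest point, thinned
to ≤ 32 candidates) is tried, and the candidate maximizing the
*noise-penalized mean silhouette* — mean silhouette of clustered points on
the precomputed distances, multiplied by the clustered fraction — wins,
ties going to the larger radius. The silhouette term rejects radii that
bridge well-separated groups; the clustered-fraction term rejects radii so
tight that legitimate group members shed off as noise. We first tried the
common k-distance-elbow rule (maximum perpendicular distance to the
endpoint chord) and found it systematically lands at the foot of the
within-group k-distance spread, leaving a quarter of the members as noise
on realistic noise levels; plateau-stability selection fails more rarely
but confuses genuinely stable plateaus with partially merged regimes, whose
apparent width is an artifact of the candidate range. Quality selection
recovers the planted partition (ARI ≥ 0.95) on 119 of 120 synthetic
draws at the default noise settings; the single failing draw was verified
to admit *no* eps value reaching 0.95, a limit of density reachability on
that sample, not of the selection. Degenerate curves: a single distinct
candidate (flat curve) is used as-is; an all-zero curve falls back to a
tiny positive radius; eps is clamped to (0, 1]. Both parameters remain
user-overridable, and the resolved values are echoed into the run metadata.

**Re-clustering** restricts the score matrix to one cluster's members and
re-runs DBSCAN (auto parameters recomputed on the submatrix when
requested); subsets too small to cluster are returned unsplit with a
warning rather than erroring.

## Summaries

Per-cluster position frequency matrices over the 22-symbol alphabet
(columns sum to 1); information content
`IC(k) = (1 − f_gap) · (log₂20 − H(k))` with the entropy over non-gap
symbols renormalized — no small-sample correction and no pseudocounts, so
closed forms are exact and testable (uniform column 0 bits, conserved
column log₂20 ≈ 4.3219 bits, 50/50 column log₂20 − 1). Consensus is the
per-position argmax with lexicographic tie-break. Logo PNG rendering is a
small optional matplotlib stacked-letter view behind `--render-logos`; the
matrices are the contract, not the plots. The 2D/3D comparison reports
per-member identity fractions over shared ids, the family mean, and
per-position mismatch tallies, with one-sided members listed separately.

## Synthetic families

The generator emulates the target situation directly: `n_groups` planted
groups whose site signatures are forced into different physicochemical
classes at ≥ `min_cross_class_positions` discriminative positions (so
groups are separable *by chemistry*, the method's premise), within-group
noise that substitutes only inside a residue's class (chemically
conservative drift), and per-position deletion at `p_gap`. Full sequences
embed the noised signature at evenly spaced scaffold offsets in a shared
uniform-random scaffold; the MSA and the per-member pairwise alignments are
column-consistent with no insertions, and a clean reference member carries
group 1's signature. Defaults (5 groups × 40 members, site length 12,
sequence length 120, p_noise 0.05, p_gap 0.02, 3 cross-class positions)
are the study conditions used throughout the tests and the acceptance
script. Seeds are mandatory; identical seeds reproduce every byte.

What the fixtures do *not* model: insertions relative to the reference,
scaffold-level divergence, alignment errors, phylogenetic correlation
between members, and realistic 3D geometry (toy structures are ideal
helices with Cα/Cβ atoms only, rise 1.5 Å, twist 100°, radius 2.3 Å, plus
one centroid-placed ligand atom). Passing tests therefore demonstrate
correctness of the bookkeeping, the scoring and the clustering under
controlled noise — not robustness to aligner or modeling errors on real
families, where the identity gate, the gap filter and the 2D/3D comparison
exist precisely to surface such problems.

## Numerical and degenerate-input choices

* Score matrices are symmetrized as `(V + Vᵀ)/2` and the diagonal zeroed to
  keep validation exact under float arithmetic.
* Percent identity of an alignment with no both-non-gap column is 0.
* PDB reading keeps only blank/'A' altlocs (single deterministic
  conformer), maps non-standard polymer residues to X, and drops water.
* All TSV/FASTA outputs are UTF-8 with LF endings; column indices are
  0-based internally, 1-based in every user-facing report.
* Problem sizes in tests and the acceptance script (families of 200,
  random DBSCAN instances n ≤ 50, 100 toy structures, 200 aligner pairs of
  length ≤ 6) were chosen so each oracle comparison is exhaustive or
  exactly checkable while the whole suite runs in seconds.

## Known limitations

* One pocket per reference; multi-reference runs require equal pocket
  lengths and assume the references' pockets correspond position-by-position.
* The 2D route gates identity on the MSA-induced pairwise alignments,
  which inherit any MSA errors.
* Auto-eps scans up to 32 DBSCAN runs (O(n²) each); for very large
  families supply eps/min_samples explicitly if this becomes noticeable.
* The default distance matrix is a documented class-based construction;
  families whose specificity hinges on finer-than-class distinctions may
  need a custom matrix via `--matrix`.
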