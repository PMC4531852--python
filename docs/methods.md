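# Methods

This note documents the models, parameters and numerical choices behind
`gssualign`, and what its synthetic-data tests do and do not establish
about real structures.

## Structure model

A structure is an ordered list of residues, each with a base (A, U, G,
C, or N for unrecognized nucleotides), its atoms, and one
representative point used by all superposition code — the backbone
phosphate P. Real 5'-terminal residues often lack a phosphate, so the
representative point falls back to O5', then C5', then C1'; a residue
with none of these is dropped with a log message. Modified nucleotides
are mapped to their parent base by a small built-in table (PSU→U,
1MA→A, ...); unknown residues that still carry a ribose C1' become N,
which keeps sequence-identity measures well defined (N never counts as
an identical base). Only altloc blank/'A' atoms are read; insertion
codes are preserved in residue identity and ordering. PDB and mmCIF are
read (gemmi); output is PDB only. Coordinates are Å throughout;
internal indices are 0-based, author numbering is kept for reporting.

## Base-pair detection

The decomposition needs canonical pairs (A-U, G-C, G-U). Two routes:

* an external annotation file (one pair per line, chain/number/icode
  for both partners) for users with 3DNA/DSSR-style annotations;
* a built-in geometric detector. A candidate pair must be complementary
  and satisfy: C1'–C1' distance in [8.0, 12.0] Å (the A-form window),
  glycosidic-face donor–acceptor distance (purine N1 to pyrimidine N3)
  ≤ 3.6 Å, base-plane normal angle ≤ 65°, and ≥ 3 intervening residues
  for intra-chain pairs (minimal hairpin loop). One pair per residue is
  enforced by greedily keeping the smallest donor–acceptor distance.

The thresholds are standard A-form geometry, chosen once; the synthetic
generator places true-pair face atoms at 3.0 Å and all non-pair face
contacts at ≥ 4.0 Å, so at zero noise detection is exact by
construction — the detector is validated against that ground truth, not
against a crystallographic annotator.

Pseudoknots: stem finding assumes nesting, so the pair list is first
reduced to a maximum-cardinality crossing-free subset by interval
dynamic programming (ties broken toward the pair with the smaller 5'
index). Residues of removed pairs are treated as unpaired.

## GSSU decomposition

Helices are maximal runs of nested pairs where consecutive pairs leave
at most 2 unpaired (bulge) residues on either strand; helices shorter
than `min_stem` (default 2 — isolated pairs are noise more often than
structure) are dissolved. A helix whose innermost pair encloses only
unpaired residues becomes a hairpin unit (neck = innermost pair, loop =
enclosed residues); a helix enclosing other helices — or nothing, as in
a blunt duplex — is a loop-less unit with no neck. Unpaired residues
between units join the flank of the unit owning the nearest preceding
paired residue (residues before the first stem join the first unit), so
the units partition the residue set exactly. A structure with no pairs
is one all-loop unit. The decomposition is a function of the pair list
and residue order only, never of coordinates.

## Pairwise superposition

Seeding: for each GSSU pair, the two neck phosphates are anchored and
every loop-residue pair (u, v) is tried as the third Kabsch point. The
3-point transform is extended to a unit-wide residue pairing —
stems matched outermost-in, loops walked outward from (u, v), flanks
matched from the stem outward — and the seed's score is the RMSD of
that pairing under the 3-point transform. The per-seed score is the
unit-wide RMSD rather than the 3-point RMSD because the latter is
nearly degenerate (three points fit almost exactly); the unit-wide
value actually ranks seeds. Ties break toward the smallest residue
indices, making seeding fully deterministic. Units without a neck/loop
still seed: loop-less stems anchor on their outermost pair and try the
innermost pair's residues as third points; all-loop units (unstructured
strands) anchor on their first/last residues and try interior ones.

The best seed over all GSSU pairs is applied to the whole second
structure, and the fit is refined by iterating: match mutual
nearest-neighbor representative points within `nn_cutoff` (default
4.0 Å — the PSI cutoff, the one distance scale the quality measures
already use), refit Kabsch on the matches, repeat until the matched set
repeats (an integer fixed point; no float tolerance) or `max_iter`
(20) is reached. Fewer than 3 mutual pairs aborts refinement and
returns the last valid transform flagged unconverged. Kabsch fits use
`scipy`'s `Rotation.align_vectors`, which guarantees a proper rotation
(no reflections).

Scoring: `s = RMSD_matched · min(|A|, |B|) / N_matched`. This is zero
for identical structures, increases with geometric deviation, and
penalizes low coverage through the min/N factor; coverage is also how a
GSSU-count mismatch between structures manifests. The score is made
exactly symmetric by always computing in a canonical argument order
(lexicographic by structure id, then residue count) and inverting the
transform for reporting when the order was swapped.

Degenerate-input fast paths: `kabsch_fit` returns the exact identity
for bitwise-identical point sets, and structure averaging keeps
bitwise-equal matched coordinates unchanged rather than recomputing
their weighted mean. Without these, ~1e-16 rounding would make
self-alignments and averages of identical copies nonzero; with them,
self-comparison is exactly 0.0 at every stage.

Known limitation: structures containing several *identical* units are
intrinsically ambiguous — a cross-unit seed is legitimately as good as
the "correct" one, and the global alignment may cover only one unit.
The coverage term in the S-distance reports this honestly (the score
rises), but the matched set is then not unique.

## Quality measures and significance

* RMSD over matched representative points after the final transform.
* PSI = 100 · |matched pairs within 4.0 Å| / min(|A|, |B|). Matched
  pairs are counted, not arbitrary near neighbors.
* PID = 100 · |matched pairs with identical base, N excluded from the
  numerator only| / min(|A|, |B|).
* n_aligned, n_exact: matched pairs, and matched pairs with identical
  (non-N) base.

The p-value is an add-one permutation estimator,
p = (1 + #{null ≤ observed}) / (n_null + 1), bounded in
[1/(n_null+1), 1], with a mandatory seed. The null re-poses each GSSU
of the second structure independently by a uniformly random rotation
about its centroid (plus a global rotation) and shuffles its base
labels, preserving geometry *within* units; it therefore measures
whether the observed alignment beats what the unit shapes alone can
achieve in a random mutual arrangement. A single whole-structure
rotation would be an empty null here, because the aligner is
rigid-motion invariant. Consequences worth knowing: for single-unit
structures the null is equivalent to the observed configuration and
p concentrates near 0.5 — the statistic is informative only when
inter-unit geometry carries signal, which is exactly what it is meant
to test.

## Multiple alignment

All n(n−1)/2 pairwise S-distances (each pair computed once; the matrix
is symmetric with a zero diagonal) feed canonical neighbor joining:
Q-criterion join selection, the standard branch-length and reduction
formulas, negative branch lengths clamped to zero, ties broken toward
the smallest cluster-index pair. On additive matrices NJ provably
recovers the generating tree; that property is tested directly, and an
independent implementation (scikit-bio's `nj`) is cross-checked in the
suite.

Merging follows the NJ join order (the first join is the Q-minimal,
most related pair). Each merge aligns the lighter cluster's average
onto the heavier one (ties: onto the first argument) and replaces
matched representative points by the weight-weighted mean; atoms of
identical-base matches are averaged name-wise, other residues keep the
heavier member's atoms; unmatched residues are inherited from the
heavier cluster, so the average's length is stable under adding
near-duplicates. The final average is re-decomposed and every input is
re-aligned against it with the full pairwise machinery (not reusing
merge-path transforms), matching the reporting semantics of per-member
panels against a consensus; members are reported in descending
S-distance order.

Thread parallelism exists only across independent pairwise alignments
(and per-member re-alignments); no summation order within a single
alignment depends on scheduling, so all outputs are bit-identical for
any thread count — this is tested, not assumed.

## Synthetic data: what it emulates, what it does not

The generator builds idealized A-form-like geometry: rise 2.8 Å per
step, twist 32.7°, 10.4 Å C1'–C1' across a pair, semicircular loops,
straight inter-hairpin linkers 30 Å apart, and only the atoms the
pipeline consumes (P, O5', C5', C1', glycosidic N, face N, C2). Stem
sequences cycle G,A,C,U; loop and linker bases are drawn from {A, G},
a set with no canonical combination, so ground-truth pairs are the
*only* detectable pairs at zero noise. Families add seeded isotropic
Gaussian noise per atom; a random-coil generator provides unstructured
controls. Everything is a pure function of spec + seed.

This validates the algorithms (decomposition, seeding, refinement,
scoring, tree building, averaging) against known answers. It does not
exercise sugar puckers, sequence-dependent helix deformation,
non-canonical pairs, tertiary contacts, crystallographic disorder or
chain breaks; passing tests show algorithmic correctness on clean
topologies, not detector parity with 3DNA/DSSR on experimental models.
For real structures with ambiguous annotation, supply an external pair
annotation file.

## Default parameters

| parameter | default | unit | role |
|---|---|---|---|
| `nn_cutoff` | 4.0 | Å | mutual-NN matching and PSI cutoff |
| `max_iter` | 20 | – | refinement cap (fixed point usually in < 5) |
| `min_stem` | 2 | bp | shortest helix kept as a stem |
| detector C1'–C1' | [8.0, 12.0] | Å | pair distance window |
| detector donor–acceptor | 3.6 | Å | face-contact threshold |
| detector plane angle | 65 | ° | base coplanarity threshold |
| `noise_sigma` (family tests) | 0.3 | Å | per-coordinate perturbation |
| `n_null` (p-values) | ≥ 19, typically 99 | – | permutation count |

Problem sizes in the test suite (hairpins of 2–6 bp stems, loops 3–8
nt, chains of up to 5 units, families of up to 5 members, p-value nulls
of 99) were chosen as the smallest instances that still exercise every
code path — seed enumeration, multi-unit selection, junction handling,
tree shapes — while keeping the whole suite fast enough to run on every
change.
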