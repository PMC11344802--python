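# Methods

## Problem and model

`kdalign` aligns pairs of protein structures treated as rigid bodies.  For
a query–subject pair it searches for the rigid-body superposition
(rotation R, translation t) that maximizes the TM-score and derives a
sequence-order-preserving residue alignment from that superposition.
Structures are represented by one representative atom per residue
(C-alpha by default); all scoring operates on these representatives.

The TM-score of an alignment with pair distances d_i, normalized by length
L, is

    TM = (1/L) * sum_i 1 / (1 + (d_i / d0(L))^2),
    d0(L) = 1.24 (L - 15)^(1/3) - 1.8,  floored at 0.5 A.

During superposition search the score is always normalized by the shorter
protein's length; results additionally report query- and subject-length
normalizations and their harmonic mean 2ab/(a+b), which is the default
database ranking measure because it discounts pairs with large length
differences.  TM >= 0.5 is used as the conventional same-fold
significance threshold.  RMSD and GDT_TS (mean fraction of aligned pairs
within 1, 2, 4, 8 A, normalized by the number of aligned pairs) are
reported per alignment.

## Superposition search

The central idea is that, given a candidate superposition, a residue
alignment can be derived without dynamic programming: each residue of the
transformed (shorter) structure independently retrieves its nearest
residue in the partner structure from an exact k-d tree.  The retrieval is
order-free; a weighted longest-increasing-subsequence pass then extracts
the best sequence-order-preserving subset (maximum count, ties by minimal
summed distance).  Order-free retrieval plus order restoration replaces
one quadratic DP per candidate with near-linear work, which is what makes
exploring thousands of candidate superpositions per pair affordable.

The staged pipeline per pair:

1. **Indexing and secondary structure.**  A k-d tree over the longer
   structure's representatives; per-residue states in {helix, strand,
   coil} from the six CA distances in the five-residue window centered on
   each residue, using the classical helix pattern
   (5.45, 5.18, 6.37, 5.45, 5.18, 5.45) ± 2.1 A and strand pattern
   (6.1, 10.4, 13, 6.1, 10.4, 6.1) ± 1.42 A; incomplete windows are coil.
2. **Fragment seeding.**  Kabsch fits of continuous equal-length fragment
   pairs (lengths {20, 50, 100} capped by the shorter length, anchors on a
   speed-dependent grid; fragment pairs with < 30% identical secondary-
   structure strings are skipped).  The best few seeds are refined with
   gap-free DP; the best TM-score so far is the *provisional* score used
   by the structure-space prescreen.
3. **Optional sequence branch** (`add_search_by_ss`): DP on a matrix of
   scaled substitution scores plus a 0.5 bonus for matching secondary-
   structure states, followed by superposition fitting; contributes to the
   tracked best only.
4. **Deep search.**  Every seed: index retrieval → Kabsch refit on the
   matches → second retrieval requiring matching secondary structure →
   order restoration → approximate ordered TM-score (uniform subsample
   capped at 512 pairs, exact below the cap).  Top 16 candidates kept by
   partial sort.
5. **DP refinement.**  For the best candidates: DP with match scores
   1/(1+(d_ij/d0)^2) given the transform (first with a secondary-structure
   bonus, then TM-only), each DP followed by superposition refits on
   differently positioned sub-fragments (full, halves, quarters) of the
   alignment, keeping the transform maximizing TM over all aligned pairs;
   iterated until the improvement falls below 1e-6 or the repetition
   budget (`convergence`, default 2) is exhausted.  Gap openings tried are
   {-0.6, 0} with extension cost 0.
6. **Statistics.**  TM under all three normalizations, RMSD and GDT_TS
   over the aligned pairs, optional secondary TM-scores (below).

The tracked best TM-score is non-decreasing across stages by
construction; the final report uses the best alignment found anywhere.

### Dynamic programming conventions

Global alignment with free end gaps (standard for superposition-driven
structure alignment): every internal run of unaligned residues on either
side costs `gap_open`, plus `gap_extend` (default 0) per additional
residue.  Traceback tie-breaks are deterministic: diagonal, then up, then
left.  A memory codec (negation for non-negative scores, constant offset
otherwise) reproduces the score write/read transform used by
memory-constrained implementations; negation round-trips bit-exactly,
offsetting is exact for integer-representable scores only.

### The speed knob

`speed` in 0..13 thins the fragment-anchor grid: anchors per structure per
fragment length = max(2, 24 − 2·speed).  Higher speeds therefore never
explore more candidate superpositions (an enforced, tested contract).
The exact depth schedule of the original accelerator implementation is
not public; only the monotone accuracy/speed trade-off is reproduced.

### Precision modes

The Kabsch rotation is solved in double precision (SVD) by default.  The
`fp32_normalized` mode emulates an accelerator-style single-precision
pipeline: coordinates cast to float32, cross-covariance K accumulated in
float32 and divided by mean(|K|) — equivalent to rescaling coordinates so
large proteins stay inside the float32 dynamic range; the scale cancels in
the rotation — followed by a closed-form trigonometric 3x3 eigensolver in
float32 (the kind of solver GPU kernels use in place of LAPACK).  Measured
over 1000 random protein-like instances, the mean elementwise rotation
difference from the double route is ~1e-7 with a tail to ~2e-5, and
TM-scores computed under either rotation agree to better than 1e-3: the
single-precision strategy is lossy but insignificantly so.  fp32
rotations are not orthogonal to better than ~1e-6; use the double mode
where strict orthogonality matters.

## Prescreens

Sequence space: the best ungapped diagonal segment score (max over all
diagonals of the maximum-sum contiguous run of substitution scores; no
DP).  The bundled table is BLOSUM62 shipped as a plain-text asset with
unknown residues scoring 0; the table is swappable via
`load_substitution_table(path)`.  Structure space: pairs whose provisional
TM-score after the seeding stage falls below `pre_score` are abandoned
before the deep search.

## Secondary TM-score (2TM)

For ranking, an alignment's TM-score can be recomputed after excluding
aligned pairs that fall in *unmatched helices*: a helix segment counts as
matched when at least half of its residues are aligned to helix-state
residues of the partner; pairs inside unmatched segments on either side
are dropped.  This definition is one reasonable operationalization of
"excluding unmatched helices"; the exclusion rule is isolated in
`filter_unmatched_helices` so it can be revised independently.

## Reference-free evaluation

`constrained_tm` scores any tool's alignment by the best superposition
*for that fixed alignment*: multi-start (full pair list and sliding
sub-fragments of lengths n, n/2, n/4) iterative subset reweighting over a
shrinking cutoff schedule (8, 7, 6, 5, 4, 3, 2, 1.5, 1 A), keeping the
transform maximizing TM over all aligned pairs; the alignment is never
altered, and the result provably dominates the plain all-pair Kabsch fit
(it is the first start).  Cumulative score curves are reported under both
the tool's own ranking and the evaluated-score ranking, with the count of
alignments at TM >= 0.5.

Classification-based evaluation computes weighted precision-recall at the
family/superfamily/fold levels of SCOPe-style sccs labels: true positives
share the level's group (but no lower-level group) and are weighted by the
reciprocal of the query group's observed (effective) size; false
positives are different-fold pairs weighted by the reciprocal effective
fold size; an optional rule ignores false positives inside the well-known
Rossmann-like (c.2–c.5, c.27, c.28, c.30, c.31) and beta-propeller
(b.66–b.70) cross-fold groups.  AUPRC integrates the curve over recall
with a recall-0 anchor.  Per-query sensitivity is the fraction of a
query's positives ranked above its first false positive.

## Synthetic fixtures

The generator emulates protein-like C-alpha geometry with known ground
truth: ideal helices (radius 2.27 A, rise 1.5 A, 100°/residue), ideal
two-periodic strands (3.05 A axial step, 0.86 A zigzag), and persistent
random-walk coils, concatenated with random segment orientations at a
3.65 A junction step; all consecutive CA distances fall in 3.2–4.0 A.
Pairs are derived by a random rigid transform plus block indels and
isotropic Gaussian noise whose `jitter_sd` is the RMS *atomic
displacement* (per-coordinate sd = jitter_sd/sqrt(3)).  Non-representative
backbone atoms are schematic fixed offsets, sufficient because every
score consumes representatives only.  Decoy sets are coil structures
certified mutually dissimilar (pairwise TM < 0.4) by the package's own
aligner at its most thorough setting.

What the fixtures do not emulate: real side chains, Ramachandran-valid
torsions, hydrogen-bond-defined secondary structure, domain packing and
compactness, or realistic sequence-structure correlation.  Passing the
synthetic suite therefore demonstrates the correctness of the search,
alignment and scoring machinery under controlled truth, not benchmark
performance on real proteomes.

## Study conditions used by tests and the acceptance script

Parameter-recovery runs use 100 pairs with domain-like lengths 60–140,
mixed architecture, up to 20% of residues edited in 1–7-residue indel
blocks, and 0.5 A displacement jitter; rotation-recovery runs use 0.3 A
jitter.  The fp32 comparison uses 1000 point sets of 10–500 points
spanning 10–500 A.  Oracle equivalences use 1e5 nearest-neighbor queries,
1e4 sampled 5x5 score matrices (exhaustive enumeration covers all 252
monotone alignments), and 1e3 random match sets against a quadratic LIS
oracle.  These sizes keep a complete run within a few minutes on one CPU
core while leaving the statistics stable across seeds.

## Numerical choices and degenerate inputs

- Nearest-neighbor ties resolve to the smaller residue index (two-nearest
  query with a 1e-9 tie band) for cross-platform determinism.
- Kabsch with < 3 points raises; coincident or collinear point sets
  return an identity-or-best-effort proper rotation flagged `degenerate`.
- DP and LIS inner loops are numba-compiled; results are independent of
  compilation (pure functions of their inputs).
- Refinement convergence tolerance is an absolute TM change of 1e-6.
- Alternate locations: first altloc kept; insertion codes in file order.
  Multi-chain files are concatenated in file order into one sequence.

## Known limitations

- Register shifts inside ideal periodic secondary structure are
  near-symmetries of the segment (helix screw, strand translation), so a
  shifted candidate alignment is a genuine local optimum of
  alignment-confined refinement; recovery comes from fragment re-seeding
  in the full pipeline, not from refinement alone.  Real helices are less
  ideal, but the same effect exists in practice.
- The secondary-structure + sequence DP branch uses fixed mixture weights
  (bonus 0.5, weight 1.0); these are exposed in `SearchParams` but have
  not been tuned against real benchmarks.
- GDT_TS here is normalized by aligned pair count, which rewards short
  precise alignments when compared across tools with different coverage;
  interpret jointly with TM-score and aligned length.
- Very short proteins (< ~20 residues) have a floored d0 of 0.5 A, making
  the TM surface sharply peaked; candidate selection by approximate
  partial sorting can then settle on near-optimal rather than optimal
  alignments.
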