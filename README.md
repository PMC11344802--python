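# kdalign

Spatial-index-driven protein structure alignment, superposition and
search.

`kdalign` is for structural bioinformaticians who need to align pairs of
protein structures, search a query against a structure database, and
evaluate alignment quality without trusting any tool's own ranking.  It
treats structures as rigid bodies and searches for the superposition
(rotation R, translation t) maximizing the TM-score

    TM = (1/L) Σᵢ 1 / (1 + (dᵢ/d₀(L))²),   d₀(L) = 1.24·(L−15)^⅓ − 1.8  (≥ 0.5 Å),

normalized by the shorter protein's length during optimization (query-
and subject-length normalizations and their harmonic mean are reported
too; TM ≥ 0.5 conventionally indicates the same fold).  The distinguishing
mechanism is that residue correspondences under a candidate superposition
are derived from an exact k-d tree — each residue independently retrieves
its spatial nearest neighbor in the partner — followed by a weighted
longest-increasing-subsequence pass that restores sequence order.  This
sidesteps one dynamic-programming pass per candidate and makes exploring
thousands of candidate superpositions per pair cheap.  Gap-penalized DP
(TM-score-based match scores, free end gaps) then refines the best
candidates to convergence.

Also included: Kabsch superposition in double and normalized
single-precision modes, geometric secondary-structure assignment,
GDT_TS and RMSD statistics, sequence- and structure-space prescreens for
database search, a reference-free evaluation harness (constrained-
superposition TM-score for *any* tool's alignments, cumulative score
curves, weighted precision–recall against SCOPe-style labels), and a
synthetic structure generator with known ground truth used throughout the
test suite.

## Worked example

```python
from kdalign import SearchParams, align_pair
from kdalign.synthetic import SyntheticSpec, make_pair

# a 40-residue helix-coil-strand structure; the subject is a rigidly
# moved copy with a 4-residue deletion and 0.4 A coordinate noise
spec = SyntheticSpec(
    architecture=(("helix", 18), ("coil", 8), ("strand", 14)),
    seed=7, jitter_sd=0.4, indels=((12, 4, "del"),),
)
q, s, true_t, truth = make_pair(spec)

res = align_pair(q, s, SearchParams(speed=9))
a = res.alignment
print(f"query length    : {len(q)}")
print(f"subject length  : {len(s)}")
print(f"aligned pairs   : {a.pairs.n_aligned}")
print(f"TM-score (short): {a.tm_short:.4f}")
print(f"TM-score (query): {a.tm_query:.4f}")
print(f"RMSD            : {a.rmsd:.3f} A")
print(f"GDT_TS          : {a.gdt_ts:.4f}")
print(f"rank measure    : {res.rank_measure:.4f}")
```

prints

```
query length    : 40
subject length  : 36
aligned pairs   : 36
TM-score (short): 0.9547
TM-score (query): 0.8674
RMSD            : 0.357 A
GDT_TS          : 1.0000
rank measure    : 0.9090
```

All 36 surviving residues are aligned; the short-normalized TM-score of
0.95 (≥ 0.5) correctly identifies the pair as same-fold, the
query-normalized score is lower because 4 of the query's 40 residues have
no counterpart, RMSD reflects the injected 0.4 Å noise, GDT_TS of 1.0
says every aligned pair sits within 1 Å after superposition, and the rank
measure is the harmonic mean of the query- and subject-normalized scores.

## Command line

```sh
# search queries against a database (files, .gz, directories or tar)
kdalign search --qrs queries/ --rfs subjects/ -o out/ -s 0.5 --speed 9

# reference-free evaluation of any tool's alignments
kdalign eval --alignments alns.tsv --structures subjects/ -o eval_out/

# write synthetic fixture structures
kdalign fixtures -o fixtures/ --count 2 --seed 1
```

`search` writes one ranked `.hits.tsv` per query (TM-scores, RMSD,
GDT_TS, aligned index pairs) plus a `manifest.json` with parameters and
prescreen counters.  Output is byte-identical across reruns with the same
inputs.  See `docs/methods.md` for the algorithm, parameter and
evaluation details.

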