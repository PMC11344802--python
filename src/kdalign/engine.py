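"""End-to-end pairwise alignment and database search.

The aligner follows a staged outline.  After spatial indexing and
secondary-structure assignment, rigid superpositions are seeded from
Kabsch fits of continuous equal-length fragment pairs; each stage that
follows can only improve the tracked best TM-score (always normalized by
the shorter protein during optimization):

1. gapless fragment seeding plus TM-driven refinement of the best seeds;
2. an optional secondary-structure + sequence-similarity DP branch;
3. a deep superposition search in which every seed is turned into an
   order-free alignment via the partner's spatial index, refit, re-matched
   with secondary-structure agreement enforced, order-restored, and scored
   approximately (capped at 512 pairs);
4. DP refinement of the best candidates using secondary-structure + TM
   match scores, then TM-only match scores, iterated to convergence;
5. final statistics (TM-scores under all normalizations, RMSD, GDT_TS and
   optionally secondary TM-scores).

Database search wraps this per-pair routine with cheap prescreens in
sequence space (best ungapped diagonal segment score) and structure space
(provisional TM-score after the seeding stage), batching, and ranking by
the harmonic mean of the query- and subject-length-normalized TM-scores.
The --speed knob shrinks the seeding grid: higher speeds explore fewer
superposition candidates and are never slower.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

from .alignment import (
    Alignment,
    StateIndex,
    approx_ordered_tm,
    default_index_cutoff,
    dp_align,
    index_align,
    restore_order,
)
from .geometry import Transform, apply_transform, kabsch
from .scoring import (
    AlignedPairSet,
    assign_ss,
    d0,
    gdt_ts,
    load_substitution_table,
    local_ss_similarity,
    tm_from_distances,
    tm_pair_scores,
    tm_score_2tm,
)
from .structure_io import Structure

__all__ = [
    "SearchParams",
    "SearchResult",
    "seed_fragment_superpositions",
    "deep_search",
    "refine_best",
    "align_pair",
    "prescreen_sequence",
    "prescreen_structure",
    "search",
]

MIN_LENGTH = 3
CONVERGENCE_TOL = 1e-6


@dataclass(frozen=True)
class SearchParams:
    """Tunable knobs of the aligner and search.

    `speed` (0-13) trades superposition-search depth for time: it thins the
    fragment-anchor grid, so higher values never explore more candidates.
    `pre_score` / `pre_similarity` enable structure- and sequence-space
    prescreens; `gap_opens` are the DP gap-opening penalties tried during
    refinement; `convergence` bounds the TM-refinement repetitions;
    `tm_output_threshold` (-s) drops weak hits; `nhits` caps reported hits
    per query.
    """

    speed: int = 9
    pre_score: float | None = None
    pre_similarity: float | None = None
    add_search_by_ss: bool = True
    gap_opens: tuple[float, ...] = (-0.6, 0.0)
    convergence: int = 2
    tm_output_threshold: float = 0.0
    nhits: int = 1000
    seed: int = 0
    use_2tm_score: bool = False
    index_cutoff: float | None = None
    ss_match_bonus: float = 0.5
    score_weight: float = 1.0
    frag_lengths: tuple[int, ...] = (20, 50, 100)
    anchors_base: int = 24
    topk_deep: int = 16
    topk_refine: int = 4
    min_frag_ss_similarity: float = 0.3
    chunk_size: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.speed <= 13):
            raise ValueError("speed must be in 0..13")

    @property
    def n_anchors(self) -> int:
        """Fragment anchors per structure per length; non-increasing in speed."""
        return max(2, self.anchors_base - 2 * self.speed)


@dataclass
class SearchResult:
    query_id: str
    subject_id: str
    alignment: Alignment
    rank_measure: float = 0.0
    secondary: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


@dataclass
class _Candidate:
    """Internal: a superposition candidate in mobile->target orientation."""

    transform: Transform
    pairs: AlignedPairSet
    tm: float


class _PairContext:
    """Shared state for aligning one (query, subject) pair.

    Internally the shorter structure is the mobile one and is always the
    side being transformed; results are flipped back to query/subject
    orientation at the end.
    """

    def __init__(self, q: Structure, s: Structure, params: SearchParams):
        if len(q) < MIN_LENGTH or len(s) < MIN_LENGTH:
            raise ValueError(
                f"structures must have >= {MIN_LENGTH} residues "
                f"(got {len(q)} and {len(s)})"
            )
        self.params = params
        self.swapped = len(q) > len(s)
        mobile, target = (s, q) if self.swapped else (q, s)
        self.mobile, self.target = mobile, target
        self.ss_mobile = mobile.ss_states if mobile.ss_states is not None else assign_ss(mobile)
        self.ss_target = target.ss_states if target.ss_states is not None else assign_ss(target)
        self.L_norm = len(mobile)
        self.d0 = d0(self.L_norm)
        self.cutoff = (
            params.index_cutoff
            if params.index_cutoff is not None
            else default_index_cutoff(self.L_norm)
        )
        self.target_index = StateIndex(target.repr_coords, self.ss_target)
        self.best: _Candidate | None = None
        self.stage_tm: list[float] = []
        self.n_explored = 0

    def track(self, cand: _Candidate) -> None:
        if self.best is None or cand.tm > self.best.tm:
            self.best = cand

    def close_stage(self) -> None:
        self.stage_tm.append(self.best.tm if self.best else 0.0)


def _anchor_positions(L: int, frag_len: int, n_anchors: int) -> np.ndarray:
    span = L - frag_len
    if span < 0:
        return np.empty(0, dtype=np.int64)
    n = min(n_anchors, span + 1)
    return np.unique(np.round(np.linspace(0, span, n)).astype(np.int64))


def seed_fragment_superpositions(
    q: Structure,
    s: Structure,
    params: SearchParams,
    ss_q: np.ndarray | None = None,
    ss_s: np.ndarray | None = None,
) -> list[tuple[Transform, int, int, int]]:
    """Superpositions from Kabsch fits of continuous fragment pairs.

    Fragments of each scheduled length (capped at 100 residues and at the
    shorter protein's length) are anchored on a speed-dependent grid over
    both structures; every anchor pair yields one transform mapping `q`'s
    fragment onto `s`'s, unless the fragments' secondary-structure strings
    are too dissimilar, which skips the fit.  Returns
    ``(transform, q_start, s_start, frag_len)`` tuples.
    """
    Lq, Ls = len(q), len(s)
    min_l = min(Lq, Ls)
    if min_l < MIN_LENGTH:
        return []
    if ss_q is None:
        ss_q = q.ss_states if q.ss_states is not None else assign_ss(q)
    if ss_s is None:
        ss_s = s.ss_states if s.ss_states is not None else assign_ss(s)
    lengths = sorted({min(fl, min_l) for fl in params.frag_lengths if fl >= MIN_LENGTH})
    seeds: list[tuple[Transform, int, int, int]] = []
    for fl in lengths:
        qa = _anchor_positions(Lq, fl, params.n_anchors)
        sa = _anchor_positions(Ls, fl, params.n_anchors)
        for i in qa:
            ss_fq = ss_q[i : i + fl]
            for j in sa:
                if (
                    local_ss_similarity(ss_fq, ss_s[j : j + fl])
                    < params.min_frag_ss_similarity
                ):
                    continue
                t = kabsch(s.repr_coords[j : j + fl], q.repr_coords[i : i + fl])
                seeds.append((t, int(i), int(j), fl))
    return seeds


def _index_candidate(
    ctx: _PairContext, t: Transform
) -> _Candidate | None:
    """One deep-search evaluation of a seed transform (mobile->target)."""
    mc = ctx.mobile.repr_coords
    qi, si, dist = index_align(mc, ctx.target_index, t, ctx.cutoff)
    if qi.size >= MIN_LENGTH:
        t = kabsch(ctx.target.repr_coords[si], mc[qi])
    qi, si, dist = index_align(
        mc,
        ctx.target_index,
        t,
        ctx.cutoff,
        require_ss_match=True,
        ss_q=ctx.ss_mobile,
        ss_s=ctx.ss_target,
    )
    apairs = restore_order(qi, si, dist)
    if apairs.n_aligned == 0:
        return None
    tm = approx_ordered_tm(apairs, ctx.L_norm)
    return _Candidate(t, apairs, tm)


def _tm_match_matrix(ctx: _PairContext, t: Transform, ss_bonus: float) -> np.ndarray:
    dmat = cdist(apply_transform(ctx.mobile.repr_coords, t), ctx.target.repr_coords)
    M = 1.0 / (1.0 + (dmat / ctx.d0) ** 2)
    if ss_bonus:
        same = ctx.ss_mobile[:, None] == ctx.ss_target[None, :]
        M = ctx.params.score_weight * M + ss_bonus * same
    return M


def _alignment_fragments(n: int) -> list[tuple[int, int]]:
    """(start, length) sub-fragments of an n-pair alignment to refit on."""
    out = [(0, n)]
    for frac in (2, 4):
        fl = n // frac
        if fl < MIN_LENGTH:
            continue
        step = max(1, n // 4)
        for start in range(0, n - fl + 1, step):
            out.append((start, fl))
    return out


def _evaluate_transform(
    ctx: _PairContext, t: Transform, qi: np.ndarray, si: np.ndarray
) -> _Candidate:
    d = np.linalg.norm(
        apply_transform(ctx.mobile.repr_coords[qi], t)
        - ctx.target.repr_coords[si],
        axis=1,
    )
    apairs = AlignedPairSet(qi, si, d)
    return _Candidate(t, apairs, tm_from_distances(d, ctx.L_norm))


def _refine_candidate(
    ctx: _PairContext,
    cand: _Candidate,
    gap_open: float,
    reps: int,
    ss_bonus: float = 0.0,
) -> _Candidate:
    """TM-driven DP + fragment-refit refinement of one candidate.

    Each repetition aligns by DP under the current superposition (match
    scores from inter-residue TM terms, optionally with a secondary-
    structure bonus), then refits the superposition on differently
    positioned sub-fragments of different lengths of that alignment,
    keeping the transform that maximizes the TM-score over all aligned
    pairs.  Stops early once the improvement falls below tolerance.
    """
    best = cand
    t = cand.transform
    for _ in range(max(1, reps)):
        prev_tm = best.tm
        M = _tm_match_matrix(ctx, t, ss_bonus)
        qi, si, _ = dp_align(M, gap_open)
        if qi.size < MIN_LENGTH:
            break
        mc = ctx.mobile.repr_coords
        tc = ctx.target.repr_coords
        for start, fl in _alignment_fragments(qi.size):
            sub_q = qi[start : start + fl]
            sub_s = si[start : start + fl]
            if sub_q.size < MIN_LENGTH:
                continue
            tf = kabsch(tc[sub_s], mc[sub_q])
            cand_f = _evaluate_transform(ctx, tf, qi, si)
            if cand_f.tm > best.tm:
                best = cand_f
        t = best.transform
        if best.tm - prev_tm < CONVERGENCE_TOL:
            break
    return best


def deep_search(
    ctx: _PairContext, seeds: list[tuple[Transform, int, int, int]]
) -> list[_Candidate]:
    """Index-driven evaluation of every seed; keeps the top candidates.

    For each seed: order-free index alignment, Kabsch refit on the matched
    pairs, a second index alignment with secondary-structure agreement
    enforced, order restoration, and an approximate ordered TM-score.  The
    `topk_deep` best candidates survive (partial sort; ties by insertion
    order).
    """
    cands: list[_Candidate] = []
    for t, *_ in seeds:
        ctx.n_explored += 1
        c = _index_candidate(ctx, t)
        if c is not None:
            cands.append(c)
    cands.sort(key=lambda c: -c.tm)
    return cands[: ctx.params.topk_deep]


def refine_best(
    ctx: _PairContext,
    candidates: list[_Candidate],
    gap_open: float,
    reps: int,
    ss_bonus: float = 0.0,
) -> _Candidate | None:
    """Refine a candidate list; returns the best refined candidate."""
    best: _Candidate | None = None
    for cand in candidates:
        refined = _refine_candidate(ctx, cand, gap_open, reps, ss_bonus=ss_bonus)
        if best is None or refined.tm > best.tm:
            best = refined
    return best


@njit(cache=True)
def _diag_kadane(M):  # pragma: no cover - exercised via prescreen_sequence
    Lq, Ls = M.shape
    best = 0.0
    for off in range(-(Lq - 1), Ls):
        run = 0.0
        i = -off if off < 0 else 0
        j = 0 if off < 0 else off
        while i < Lq and j < Ls:
            run += M[i, j]
            if run < 0.0:
                run = 0.0
            elif run > best:
                best = run
            i += 1
            j += 1
    return best


def prescreen_sequence(
    q: Structure, s: Structure, threshold: float
) -> tuple[bool, float]:
    """Best local ungapped diagonal segment score between the sequences.

    The maximum over all diagonals of the maximum-sum contiguous segment of
    substitution scores; no dynamic programming, no gaps.  Passes when the
    score reaches `threshold`.
    """
    table = load_substitution_table()
    M = table.pair_matrix(q.sequence, s.sequence)
    score = float(_diag_kadane(np.ascontiguousarray(M)))
    return score >= threshold, score


def prescreen_structure(provisional_tm: float, threshold: float) -> bool:
    """Structure-space prescreen on the provisional (seeding-stage) TM."""
    return provisional_tm >= threshold


def _finalize(ctx: _PairContext, q: Structure, s: Structure) -> SearchResult:
    params = ctx.params
    best = ctx.best
    assert best is not None
    mi, ti, dist = best.pairs.q_indices, best.pairs.s_indices, best.pairs.distances
    if ctx.swapped:
        q_idx, s_idx = ti, mi
        transform = best.transform.inverse()
    else:
        q_idx, s_idx = mi, ti
        transform = best.transform
    apairs = AlignedPairSet(q_idx, s_idx, dist)
    tm_short, tm_q, tm_s, hmean = tm_pair_scores(apairs, len(q), len(s))
    ss_q = ctx.ss_target if ctx.swapped else ctx.ss_mobile
    ss_s = ctx.ss_mobile if ctx.swapped else ctx.ss_target
    aln = Alignment(
        pairs=apairs,
        transform=transform,
        tm_short=tm_short,
        tm_query=tm_q,
        tm_subject=tm_s,
        rmsd=float(np.sqrt(np.mean(dist**2))) if dist.size else 0.0,
        gdt_ts=gdt_ts(apairs) if apairs.n_aligned else 0.0,
        extras={
            "stage_tm": list(ctx.stage_tm),
            "n_explored": ctx.n_explored,
            "n_aligned": apairs.n_aligned,
        },
    )
    secondary: dict = {}
    measure = hmean
    if params.use_2tm_score:
        tm2_q = tm_score_2tm(apairs, ss_q, ss_s, len(q))
        tm2_s = tm_score_2tm(apairs, ss_q, ss_s, len(s))
        denom = tm2_q + tm2_s
        h2 = 0.0 if denom == 0.0 else 2 * tm2_q * tm2_s / denom
        secondary = {"tm2_query": tm2_q, "tm2_subject": tm2_s, "harmonic_2tm": h2}
        measure = h2
    return SearchResult(
        query_id=q.id,
        subject_id=s.id,
        alignment=aln,
        rank_measure=measure,
        secondary=secondary,
        extras={"harmonic_tm": hmean},
    )


def align_pair(
    q: Structure, s: Structure, params: SearchParams | None = None
) -> SearchResult:
    """Align one query-subject pair through the full staged pipeline.

    Both structures must be preprocessed.  The returned result carries the
    alignment in query/subject orientation, the transform mapping query
    coordinates onto the subject frame, TM-scores under all three
    normalizations, RMSD and GDT_TS over the aligned pairs, and (when
    enabled) secondary TM-scores.  Raises for structures shorter than 3
    residues.  When ``params.pre_score`` is set and the provisional
    TM-score after the seeding stage falls below it, the pair is abandoned
    and the result is flagged ``prescreened``.
    """
    params = params or SearchParams()
    ctx = _PairContext(q, s, params)

    # stage A: gapless fragment seeding + refinement of the best seeds
    seeds = seed_fragment_superpositions(
        ctx.mobile, ctx.target, params, ctx.ss_mobile, ctx.ss_target
    )
    quick: list[_Candidate] = []
    for t, *_ in seeds:
        ctx.n_explored += 1
        qi, si, dist = index_align(ctx.mobile.repr_coords, ctx.target_index, t, ctx.cutoff)
        apairs = restore_order(qi, si, dist)
        if apairs.n_aligned:
            quick.append(_Candidate(t, apairs, approx_ordered_tm(apairs, ctx.L_norm)))
    quick.sort(key=lambda c: -c.tm)
    refined = refine_best(ctx, quick[: params.topk_refine], gap_open=0.0, reps=1)
    if refined is not None:
        ctx.track(refined)
    ctx.close_stage()
    provisional_tm = ctx.stage_tm[-1]

    if params.pre_score is not None and not prescreen_structure(
        provisional_tm, params.pre_score
    ):
        if ctx.best is None:
            ctx.best = _Candidate(Transform.identity(), AlignedPairSet.empty(), 0.0)
        res = _finalize(ctx, q, s)
        res.extras["prescreened"] = True
        res.extras["provisional_tm"] = provisional_tm
        return res

    # stage B: optional secondary-structure + sequence-similarity DP branch
    if params.add_search_by_ss:
        table = load_substitution_table()
        mseq = table.pair_matrix(ctx.mobile.sequence, ctx.target.sequence)
        mseq = mseq / table.max_score
        same = ctx.ss_mobile[:, None] == ctx.ss_target[None, :]
        M = params.score_weight * mseq + params.ss_match_bonus * same
        for go in sorted(params.gap_opens):
            qi, si, _ = dp_align(M, go)
            if qi.size < MIN_LENGTH:
                continue
            t = kabsch(
                ctx.target.repr_coords[si], ctx.mobile.repr_coords[qi]
            )
            cand = _evaluate_transform(ctx, t, qi, si)
            ctx.track(_refine_candidate(ctx, cand, go, reps=1))
    ctx.close_stage()

    # stage C: deep superposition search through the spatial index
    cands = deep_search(ctx, seeds)
    for c in cands[: params.topk_refine]:
        ctx.track(c)
    ctx.close_stage()

    # stage D: DP refinement with ss+TM scores, then TM-only to convergence
    top = cands[: params.topk_refine]
    if ctx.best is not None and all(ctx.best is not c for c in top):
        top = [ctx.best] + top
    for go in sorted(params.gap_opens):
        r = refine_best(ctx, top, go, reps=1, ss_bonus=params.ss_match_bonus)
        if r is not None:
            ctx.track(r)
    ctx.close_stage()
    if ctx.best is not None:
        for go in sorted(params.gap_opens):
            ctx.track(
                _refine_candidate(ctx, ctx.best, go, reps=max(1, params.convergence))
            )
    ctx.close_stage()

    if ctx.best is None or ctx.best.pairs.n_aligned == 0:
        ctx.best = _Candidate(Transform.identity(), AlignedPairSet.empty(), 0.0)
    res = _finalize(ctx, q, s)
    res.extras["provisional_tm"] = provisional_tm
    return res


def search(
    queries: list[Structure],
    subjects: list[Structure],
    params: SearchParams | None = None,
) -> tuple[dict[str, list[SearchResult]], dict]:
    """All-vs-all batched search with prescreens, filtering and ranking.

    Queries and subjects are processed in length-sorted chunks (chunk size
    configurable; results are independent of chunking and input order).
    Per query, hits with ``max(tm_query, tm_subject)`` below the output
    threshold are dropped, the rest are ranked by the configured measure
    (harmonic-mean TM-score by default, its secondary-TM variant with
    ``use_2tm_score``) descending with ties broken by subject id, and the
    top `nhits` are kept.  Returns ``(per-query results, counters)``.
    """
    params = params or SearchParams()
    if not queries or not subjects:
        raise ValueError("search requires at least one query and one subject")
    counters = {
        "pairs_total": 0,
        "prescreen_sequence_filtered": 0,
        "prescreen_structure_filtered": 0,
        "below_output_threshold": 0,
    }
    hits: dict[str, list[SearchResult]] = {q.id: [] for q in queries}
    chunk = params.chunk_size or len(subjects)
    subjects_sorted = sorted(subjects, key=lambda s: (len(s), s.id))
    queries_sorted = sorted(queries, key=lambda s: (len(s), s.id))
    for start in range(0, len(subjects_sorted), chunk):
        batch = subjects_sorted[start : start + chunk]
        for q in queries_sorted:
            for s in batch:
                counters["pairs_total"] += 1
                if params.pre_similarity is not None:
                    ok, _score = prescreen_sequence(q, s, params.pre_similarity)
                    if not ok:
                        counters["prescreen_sequence_filtered"] += 1
                        continue
                res = align_pair(q, s, params)
                if res.extras.get("prescreened"):
                    counters["prescreen_structure_filtered"] += 1
                    continue
                aln = res.alignment
                if max(aln.tm_query, aln.tm_subject) < params.tm_output_threshold:
                    counters["below_output_threshold"] += 1
                    continue
                hits[q.id].append(res)
    for qid in hits:
        hits[qid].sort(key=lambda r: (-r.rank_measure, r.subject_id))
        hits[qid] = hits[qid][: params.nhits]
    return hits, counters
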