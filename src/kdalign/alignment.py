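"""Alignment production.

Two complementary routes produce residue correspondences:

* **Index-based matching** (`index_align`): under a candidate superposition,
  every residue of the mobile structure independently retrieves its nearest
  neighbor in the partner's k-d tree.  This is sequence-order-free and
  runs in near-constant time per residue; `restore_order` then extracts the
  best sequence-order-preserving subset (a weighted longest increasing
  subsequence).

* **Dynamic programming** (`dp_align`): gap-penalized global alignment over
  an arbitrary match-score matrix with free end gaps, affine gap cost
  (opening penalty; extension cost 0 unless specified) and a deterministic
  traceback (diagonal preferred over up over left).

`approx_ordered_tm` estimates the TM-score of long ordered alignments from
a uniform subsample capped at 512 pairs, as used during the candidate
search stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .geometry import SpatialIndex, Transform, apply_transform, build_index, query_nearest
from .scoring import AlignedPairSet, d0, tm_from_distances

__all__ = [
    "ScoreMatrix",
    "Alignment",
    "dp_align",
    "index_align",
    "restore_order",
    "approx_ordered_tm",
    "StateIndex",
    "MemoryCodec",
    "default_index_cutoff",
]


@dataclass
class ScoreMatrix:
    """L_q x L_s match scores plus a tag naming the scoring function."""

    values: np.ndarray
    provenance: str = "tm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("score matrix must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score matrix must be finite everywhere")


@dataclass
class Alignment:
    """A finished alignment with its superposition and summary statistics."""

    pairs: AlignedPairSet
    transform: Transform
    tm_short: float = 0.0
    tm_query: float = 0.0
    tm_subject: float = 0.0
    rmsd: float = 0.0
    gdt_ts: float = 0.0
    extras: dict = field(default_factory=dict)


class MemoryCodec:
    """Score write/read transform used to shrink DP memory footprints.

    ``negate`` stores non-negative scores as their negation; ``offset``
    subtracts a large constant so potentially negative scores map into a
    single sign.  Decoding inverts the operation before use.
    """

    def __init__(self, mode: str = "negate", constant: float = 65536.0):
        if mode not in ("negate", "offset"):
            raise ValueError(f"unknown codec mode {mode!r}")
        self.mode = mode
        self.constant = constant

    def encode(self, values: np.ndarray) -> np.ndarray:
        if self.mode == "negate":
            return -values
        return values - self.constant

    def decode(self, stored: np.ndarray) -> np.ndarray:
        if self.mode == "negate":
            return -stored
        return stored + self.constant


_NEG = -1e30


@njit(cache=True)
def _gotoh_fill(M, go, ge):  # pragma: no cover - exercised via dp_align
    Lq, Ls = M.shape
    Hm = np.full((Lq + 1, Ls + 1), _NEG)
    E = np.full((Lq + 1, Ls + 1), _NEG)
    F = np.full((Lq + 1, Ls + 1), _NEG)
    bH = np.zeros((Lq + 1, Ls + 1), dtype=np.int8)  # 0 start,1 diag,2 F,3 E
    bE = np.zeros((Lq + 1, Ls + 1), dtype=np.int8)  # 1 open, 2 extend
    bF = np.zeros((Lq + 1, Ls + 1), dtype=np.int8)  # 1 open, 2 extend, 3 from E
    for i in range(1, Lq + 1):
        for j in range(1, Ls + 1):
            # gap run consuming subject residues (left moves)
            e_open = Hm[i, j - 1] + go
            e_ext = E[i, j - 1] + ge
            if e_open >= e_ext:
                E[i, j] = e_open
                bE[i, j] = 1
            else:
                E[i, j] = e_ext
                bE[i, j] = 2
            # gap run consuming query residues (up moves); may follow an
            # E-run so that double-sided gaps charge both openings
            f_open = Hm[i - 1, j] + go
            f_ext = F[i - 1, j] + ge
            f_cross = E[i - 1, j] + go
            F[i, j] = f_open
            bF[i, j] = 1
            if f_ext > F[i, j]:
                F[i, j] = f_ext
                bF[i, j] = 2
            if f_cross > F[i, j]:
                F[i, j] = f_cross
                bF[i, j] = 3
            # best way to precede the pair (i, j); ties prefer the diagonal,
            # then up (F), then left (E), then a fresh start
            prev = Hm[i - 1, j - 1]
            code = 1
            if F[i - 1, j - 1] > prev:
                prev = F[i - 1, j - 1]
                code = 2
            if E[i - 1, j - 1] > prev:
                prev = E[i - 1, j - 1]
                code = 3
            if 0.0 > prev:
                prev = 0.0
                code = 0
            Hm[i, j] = M[i - 1, j - 1] + prev
            bH[i, j] = code
    return Hm, E, F, bH, bE, bF


def dp_align(
    m: ScoreMatrix | np.ndarray,
    gap_open: float,
    gap_extend: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal sequence-order-preserving alignment of a score matrix.

    Maximizes the sum of match scores plus gap terms, where every internal
    run of unaligned residues on either side costs ``gap_open`` plus
    ``gap_extend`` per additional residue; end gaps are free, as is standard
    for structure superposition alignments.  Returns ``(q_indices,
    s_indices, score)`` with both index arrays strictly increasing; the
    empty alignment (score 0) is returned when no pair is worth aligning.

    Ties are broken deterministically: the traceback prefers the diagonal
    move, then up, then left, and among equal-scoring end cells the one with
    the smallest query then subject index.
    """
    values = m.values if isinstance(m, ScoreMatrix) else np.asarray(m, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("dp_align requires a non-empty 2-D score matrix")
    Hm, E, F, bH, bE, bF = _gotoh_fill(
        np.ascontiguousarray(values), float(gap_open), float(gap_extend)
    )
    best = 0.0
    bi = bj = 0
    Lq, Ls = values.shape
    for i in range(1, Lq + 1):
        for j in range(1, Ls + 1):
            if Hm[i, j] > best:
                best = Hm[i, j]
                bi, bj = i, j
    if bi == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), 0.0
    qi: list[int] = []
    si: list[int] = []
    i, j = bi, bj
    while i > 0 and j > 0:
        qi.append(i - 1)
        si.append(j - 1)
        code = bH[i, j]
        i, j = i - 1, j - 1
        if code == 0:
            break
        if code == 1:
            continue
        # walk the gap run(s) back to the previous aligned pair
        state = code  # 2 = F, 3 = E
        while state != 0:
            if state == 2:
                b = bF[i, j]
                i -= 1
                if b == 1:
                    state = 0
                elif b == 3:
                    state = 3
            else:
                b = bE[i, j]
                j -= 1
                if b == 1:
                    state = 0
    return (
        np.array(qi[::-1], dtype=np.int64),
        np.array(si[::-1], dtype=np.int64),
        float(best),
    )


class StateIndex:
    """Spatial index with per-secondary-structure-state subtrees.

    Supports plain nearest-residue retrieval and retrieval restricted to
    residues sharing a given secondary-structure state.
    """

    def __init__(self, coords: np.ndarray, ss: np.ndarray | None = None):
        self.index = build_index(coords)
        self.ss = np.asarray(ss) if ss is not None else None
        self._by_state: dict[str, tuple[SpatialIndex, np.ndarray]] = {}
        if self.ss is not None:
            for state in ("H", "E", "C"):
                members = np.flatnonzero(self.ss == state)
                if members.size:
                    self._by_state[state] = (
                        build_index(coords[members]),
                        members,
                    )

    def query(
        self, points: np.ndarray, cutoff: float, state: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Nearest residues; `state` restricts each point to same-state hits."""
        if state is None:
            return query_nearest(self.index, points, cutoff)
        points = np.atleast_2d(points)
        out_i = np.full(points.shape[0], -1, dtype=np.int64)
        out_d = np.full(points.shape[0], np.inf)
        state = np.asarray(state)
        for st in ("H", "E", "C"):
            mask = state == st
            if not np.any(mask) or st not in self._by_state:
                continue
            sub, members = self._by_state[st]
            ii, dd = query_nearest(sub, points[mask], cutoff)
            hit = ii >= 0
            gi = np.flatnonzero(mask)
            out_i[gi[hit]] = members[ii[hit]]
            out_d[gi[hit]] = dd[hit]
        return out_i, out_d


def default_index_cutoff(L_norm: int) -> float:
    """Retrieval cutoff for index matching: d0-scaled, capped at 8 A."""
    return float(min(d0(L_norm) * 1.5, 8.0))


def index_align(
    q_coords: np.ndarray,
    s_index: StateIndex | SpatialIndex,
    t: Transform,
    cutoff: float,
    require_ss_match: bool = False,
    ss_q: np.ndarray | None = None,
    ss_s: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Order-free residue matches under a candidate superposition.

    Each residue of `q_coords` (mapped through `t` into the indexed frame)
    independently retrieves its nearest indexed residue within `cutoff`;
    with `require_ss_match` only residues of identical secondary-structure
    state are eligible.  Returns ``(q_idx, s_idx, dist)`` for the residues
    that found a match; several query residues may hit the same indexed
    residue at this stage.
    """
    moved = apply_transform(q_coords, t)
    if isinstance(s_index, SpatialIndex):
        s_index = StateIndex(s_index.coords, ss_s)
    state = None
    if require_ss_match:
        if ss_q is None or s_index.ss is None:
            raise ValueError("ss states required for ss-matched retrieval")
        state = ss_q
    idx, dist = s_index.query(moved, cutoff, state=state)
    hit = idx >= 0
    q_idx = np.flatnonzero(hit).astype(np.int64)
    return q_idx, idx[hit], dist[hit]


@njit(cache=True)
def _lis_core(s_idx, dist):  # pragma: no cover - exercised via restore_order
    n = s_idx.shape[0]
    best_len = np.ones(n, dtype=np.int64)
    best_w = dist.copy()
    parent = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        for j in range(i):
            if s_idx[j] < s_idx[i] and (
                best_len[j] + 1 > best_len[i]
                or (
                    best_len[j] + 1 == best_len[i]
                    and best_w[j] + dist[i] < best_w[i]
                )
            ):
                best_len[i] = best_len[j] + 1
                best_w[i] = best_w[j] + dist[i]
                parent[i] = j
    end = 0
    for i in range(1, n):
        if best_len[i] > best_len[end] or (
            best_len[i] == best_len[end] and best_w[i] < best_w[end]
        ):
            end = i
    out = np.empty(best_len[end], dtype=np.int64)
    k = best_len[end] - 1
    while end >= 0:
        out[k] = end
        end = parent[end]
        k -= 1
    return out


def restore_order(
    q_idx: np.ndarray, s_idx: np.ndarray, dist: np.ndarray
) -> AlignedPairSet:
    """Best sequence-order-preserving subset of raw index matches.

    Matches must arrive sorted by query index.  Collisions (several query
    residues matched to one subject residue) are first resolved in favor of
    the spatially closest query residue; a weighted longest-increasing-
    subsequence then keeps the largest strictly monotone subset, breaking
    size ties by the smallest summed distance.
    """
    q_idx = np.asarray(q_idx, dtype=np.int64)
    s_idx = np.asarray(s_idx, dtype=np.int64)
    dist = np.asarray(dist, dtype=float)
    if q_idx.size == 0:
        return AlignedPairSet.empty()
    if np.any(np.diff(q_idx) <= 0):
        raise ValueError("matches must be sorted by strictly increasing q index")
    # collision resolution: keep the closest q per subject residue
    keep = np.ones(q_idx.size, dtype=bool)
    order = np.lexsort((q_idx, dist, s_idx))
    seen: set[int] = set()
    for k in order:
        s = int(s_idx[k])
        if s in seen:
            keep[k] = False
        else:
            seen.add(s)
    q_idx, s_idx, dist = q_idx[keep], s_idx[keep], dist[keep]
    sel = _lis_core(s_idx, dist)
    return AlignedPairSet(q_idx[sel], s_idx[sel], dist[sel])


def approx_ordered_tm(
    apairs: AlignedPairSet,
    L_norm: int,
    cap: int = 512,
) -> float:
    """TM-score estimated from at most `cap` uniformly strided pairs.

    Exact whenever the alignment has at most `cap` pairs; otherwise the
    per-pair score sum is estimated from a uniform subsample that includes
    both alignment ends and rescaled to the full pair count.
    """
    n = apairs.n_aligned
    if n <= cap:
        return tm_from_distances(apairs.distances, L_norm)
    take = np.unique(np.round(np.linspace(0, n - 1, cap)).astype(np.int64))
    sub = apairs.distances[take]
    scale = d0(L_norm)
    per_pair = np.mean(1.0 / (1.0 + (sub / scale) ** 2))
    return float(per_pair * n / L_norm)
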