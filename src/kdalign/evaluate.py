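"""Reference-free and classification-based evaluation of alignments.

The reference-free harness scores any tool's alignments by how well they
translate into spatial agreement: for each fixed alignment the superposition
maximizing the TM-score is found *without changing the alignment*
(`constrained_tm`), and cumulative score curves are drawn against the
number of top hits under both the tool's own ranking and the evaluated-TM
ranking (`cumulative_curve`).

The classification-based harness computes weighted precision-recall against
a family/superfamily/fold hierarchy (SCOPe-style sccs labels), with
true-positive weights inversely proportional to effective group sizes,
false positives between folds (optionally ignoring listed cross-fold
relationships such as the Rossman-like and beta-propeller groups), and
per-query sensitivity up to the first false positive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import Transform, apply_transform, kabsch
from .scoring import AlignedPairSet, d0, tm_from_distances
from .structure_io import Structure

__all__ = [
    "LabeledPair",
    "constrained_tm",
    "cumulative_curve",
    "weighted_pr",
    "sensitivity_to_first_fp",
    "parse_sccs",
    "read_alignment_tsv",
    "write_curve_tsv",
]

# absolute distance cutoffs (A) for the shrinking-subset schedule of the
# constrained superposition optimizer; each restart fits on the pairs within
# the cutoff under the current best superposition
_CUTOFF_SCHEDULE = (8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.5, 1.0)
_MAX_INNER_ITER = 10


def constrained_tm(
    apairs: AlignedPairSet,
    q: Structure,
    s: Structure,
    L_norm: int | None = None,
) -> tuple[float, float, Transform]:
    """Best TM-score superposition for a *fixed* alignment.

    Multi-start iterative subset reweighting: superpositions are seeded
    from Kabsch fits on the full pair list and on sliding sub-fragments of
    it (lengths n, n/2, n/4), and each seed is refined by repeatedly
    refitting on the pairs within a shrinking schedule of distance cutoffs,
    keeping the transform whose TM-score over *all* aligned pairs is
    highest.  The alignment itself is never altered.  Returns
    ``(tm, rmsd, transform)`` with RMSD computed over all aligned pairs
    under the best transform; TM is normalized by `L_norm` (shorter length
    by default).
    """
    n = apairs.n_aligned
    if n < 3:
        raise ValueError("constrained superposition requires >= 3 aligned pairs")
    if L_norm is None:
        L_norm = min(len(q), len(s))
    qc = q.repr_coords[apairs.q_indices]
    sc = s.repr_coords[apairs.s_indices]

    def fit_eval(sel: np.ndarray) -> tuple[float, np.ndarray, Transform]:
        t = kabsch(sc[sel], qc[sel])
        dist = np.linalg.norm(apply_transform(qc, t) - sc, axis=1)
        return tm_from_distances(dist, L_norm), dist, t

    starts: list[np.ndarray] = [np.arange(n)]
    for fl in (n // 2, n // 4):
        if fl < 3:
            continue
        for st in range(0, n - fl + 1, max(1, n // 4)):
            starts.append(np.arange(st, st + fl))
    best_tm, best_dist, best_t = fit_eval(starts[0])
    for sel0 in starts:
        tm, dist, t = fit_eval(sel0)
        if tm > best_tm:
            best_tm, best_dist, best_t = tm, dist, t
        for cutoff in _CUTOFF_SCHEDULE:
            sel = np.flatnonzero(dist <= cutoff)
            if sel.size < 3:
                break
            prev_sel = None
            for _ in range(_MAX_INNER_ITER):
                tm, dist, t = fit_eval(sel)
                if tm > best_tm:
                    best_tm, best_dist, best_t = tm, dist, t
                new_sel = np.flatnonzero(dist <= cutoff)
                if new_sel.size < 3 or (
                    prev_sel is not None and np.array_equal(new_sel, prev_sel)
                ):
                    break
                prev_sel = sel
                sel = new_sel
    rmsd_val = float(np.sqrt(np.mean(best_dist**2)))
    return best_tm, rmsd_val, best_t


def cumulative_curve(
    measures: np.ndarray,
    scores: np.ndarray,
    threshold: float = 0.5,
) -> dict:
    """Cumulative evaluated scores against the number of top alignments.

    `measures` is the tool's own ranking value (higher = better) and
    `scores` the independently evaluated score (e.g. constrained TM) of the
    same alignments.  Returns prefix sums of `scores` under (i) the tool's
    ranking and (ii) the evaluated-score ranking, plus the number of
    alignments with an evaluated score at or above `threshold`.
    """
    measures = np.asarray(measures, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if measures.shape != scores.shape:
        raise ValueError("measures and scores must have equal length")
    by_measure = np.argsort(-measures, kind="stable")
    by_score = np.argsort(-scores, kind="stable")
    return {
        "by_measure": np.cumsum(scores[by_measure]),
        "by_score": np.cumsum(scores[by_score]),
        "n_above_threshold": int(np.sum(scores >= threshold)),
    }


def parse_sccs(sccs: str) -> tuple[str, str, str, str]:
    """Split an sccs label like ``a.1.1.2`` into class/fold/sf/family keys."""
    parts = sccs.strip().split(".")
    if len(parts) < 4:
        raise ValueError(f"not a class.fold.superfamily.family label: {sccs!r}")
    cl = parts[0]
    fold = ".".join(parts[:2])
    sf = ".".join(parts[:3])
    fam = ".".join(parts[:4])
    return cl, fold, sf, fam


# well-known cross-fold relationships ignored as false positives: the
# Rossman-like folds and the beta-propeller folds each behave as one group
ROSSMANN_FOLDS = frozenset({"c.2", "c.3", "c.4", "c.5", "c.27", "c.28", "c.30", "c.31"})
BETA_PROPELLER_FOLDS = frozenset({"b.66", "b.67", "b.68", "b.69", "b.70"})


@dataclass
class LabeledPair:
    """One ranked query-subject hit with classification labels per side."""

    query_id: str
    subject_id: str
    measure: float
    sccs_query: str
    sccs_subject: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.query_id == self.subject_id:
            raise ValueError("self-matches are excluded from labeled pairs")


_LEVELS = {"family": 3, "superfamily": 2, "fold": 1}


def _level_keys(sccs: str, level: str) -> tuple[str, str | None]:
    """(group key or None when not a TP candidate, fold key)."""
    cl, fold, sf, fam = parse_sccs(sccs)
    return {"family": fam, "superfamily": sf, "fold": fold}[level], fold


def _is_tp(sq: str, ss: str, level: str) -> bool:
    q = parse_sccs(sq)
    s = parse_sccs(ss)
    if level == "family":
        return q[3] == s[3]
    if level == "superfamily":
        return q[2] == s[2] and q[3] != s[3]
    if level == "fold":
        return q[1] == s[1] and q[2] != s[2]
    raise ValueError(f"unknown level {level!r}")


def _crossfold_exempt(fold_q: str, fold_s: str) -> bool:
    for group in (ROSSMANN_FOLDS, BETA_PROPELLER_FOLDS):
        if fold_q in group and fold_s in group:
            return True
    return False


def weighted_pr(
    pairs: list[LabeledPair],
    level: str,
    fp_rule: str = "strict",
    all_positives: list[tuple[str, str]] | None = None,
) -> dict:
    """Weighted precision-recall curve and its area at one hierarchy level.

    Pairs must arrive sorted by measure, best first.  A hit is a TP when
    both sides share the `level` group (but not any lower-level group) and
    an FP when their folds differ; with ``fp_rule="exclude_crossfold_list"``
    FPs between folds of the same listed cross-fold group are ignored.
    Other combinations (same fold but related at a lower level) are neither.
    TP counts are downweighted by the effective (observed) size of the
    query's `level` group, FP counts by the effective size of the query's
    fold.  `all_positives` optionally supplies the full positive set
    ``(sccs_q, sccs_s)`` for the recall denominator; by default the ranked
    list's own positives are used.  Returns precision/recall arrays and the
    trapezoidal AUPRC over recall.
    """
    if level not in _LEVELS:
        raise ValueError(f"level must be one of {sorted(_LEVELS)}")
    if fp_rule not in ("strict", "exclude_crossfold_list"):
        raise ValueError(f"unknown fp_rule {fp_rule!r}")
    # effective group sizes observed across both sides of the supplied pairs
    group_members: dict[str, set[str]] = {}
    fold_members: dict[str, set[str]] = {}
    for p in pairs:
        for sid, sccs in ((p.query_id, p.sccs_query), (p.subject_id, p.sccs_subject)):
            gk, fk = _level_keys(sccs, level)
            group_members.setdefault(gk, set()).add(sid)
            fold_members.setdefault(fk, set()).add(sid)

    def tp_weight(sccs_q: str) -> float:
        gk, _ = _level_keys(sccs_q, level)
        return 1.0 / max(1, len(group_members.get(gk, ())))

    def fp_weight(sccs_q: str) -> float:
        _, fk = _level_keys(sccs_q, level)
        return 1.0 / max(1, len(fold_members.get(fk, ())))

    pos_source = (
        all_positives
        if all_positives is not None
        else [(p.sccs_query, p.sccs_subject) for p in pairs]
    )
    P = sum(
        tp_weight(sq) for sq, ss in pos_source if _is_tp(sq, ss, level)
    )
    if P <= 0:
        raise ValueError(f"no positive pairs at the {level} level; recall undefined")
    wtp = 0.0
    wfp = 0.0
    precision: list[float] = []
    recall: list[float] = []
    for p in pairs:
        if _is_tp(p.sccs_query, p.sccs_subject, level):
            wtp += tp_weight(p.sccs_query)
        else:
            fq = parse_sccs(p.sccs_query)[1]
            fs = parse_sccs(p.sccs_subject)[1]
            if fq != fs:
                if fp_rule == "exclude_crossfold_list" and _crossfold_exempt(fq, fs):
                    pass
                else:
                    wfp += fp_weight(p.sccs_query)
        if wtp + wfp > 0:
            precision.append(wtp / (wtp + wfp))
            recall.append(wtp / P)
    precision_a = np.array(precision)
    recall_a = np.array(recall)
    if recall_a.size:
        # anchor the curve at recall 0 with the initial precision
        pr_full = np.concatenate([[precision_a[0]], precision_a])
        rc_full = np.concatenate([[0.0], recall_a])
        auprc = float(np.trapezoid(pr_full, rc_full))
    else:
        auprc = 0.0
    return {"precision": precision_a, "recall": recall_a, "auprc": auprc}


def sensitivity_to_first_fp(pairs: list[LabeledPair], level: str = "fold") -> dict[str, float]:
    """Per-query fraction of positives ranked above the first false positive.

    Pairs must be sorted by measure, best first.  Positives here are pairs
    related at `level` or below (same fold); false positives are different-
    fold pairs.  A query with no FP in its list scores 1.
    """
    by_query: dict[str, list[LabeledPair]] = {}
    for p in pairs:
        by_query.setdefault(p.query_id, []).append(p)
    out: dict[str, float] = {}
    for qid, plist in by_query.items():
        fold_pairs = [
            parse_sccs(p.sccs_query)[1] == parse_sccs(p.sccs_subject)[1]
            for p in plist
        ]
        n_pos = sum(fold_pairs)
        if n_pos == 0:
            continue
        before = 0
        for is_pos in fold_pairs:
            if is_pos:
                before += 1
            else:
                break
        out[qid] = before / n_pos
    return out


def read_alignment_tsv(path: str | Path) -> list[dict]:
    """Read a documented alignment TSV.

    Columns: ``query``, ``subject``, ``measure``, and either ``pairs``
    (semicolon-separated ``q:s`` 0-based index pairs) or the pair of
    ``qaln``/``saln`` gapped sequence columns (gaps as ``-``), from which
    index pairs are reconstructed.  Parse errors report the line number.
    """
    path = Path(path)
    rows: list[dict] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for ln, row in enumerate(reader, start=2):
            try:
                rec = {
                    "query": row["query"],
                    "subject": row["subject"],
                    "measure": float(row["measure"]),
                }
                if row.get("pairs"):
                    pairs = [
                        (int(a), int(b))
                        for a, b in (
                            tok.split(":") for tok in row["pairs"].split(";") if tok
                        )
                    ]
                elif row.get("qaln") and row.get("saln"):
                    pairs = []
                    qi = si = 0
                    for ca, cb in zip(row["qaln"], row["saln"]):
                        if ca != "-" and cb != "-":
                            pairs.append((qi, si))
                        if ca != "-":
                            qi += 1
                        if cb != "-":
                            si += 1
                else:
                    raise KeyError("pairs or qaln/saln")
                rec["pairs"] = pairs
                rows.append(rec)
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{ln}: malformed alignment row: {exc}") from exc
    return rows


def write_curve_tsv(path: str | Path, curve: dict) -> None:
    """Write a cumulative curve as a rank/by_measure/by_score TSV."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["rank", "cumulative_by_measure", "cumulative_by_score"])
        for i, (a, b) in enumerate(zip(curve["by_measure"], curve["by_score"]), 1):
            w.writerow([i, f"{a:.6f}", f"{b:.6f}"])
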