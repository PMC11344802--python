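"""Scalar similarity scores: TM-score family, GDT_TS, secondary structure.

The TM-score of an alignment with pair distances :math:`d_i` normalized by
length :math:`L` is

.. math:: \\mathrm{TM} = \\frac{1}{L} \\sum_i \\frac{1}{1 + (d_i/d_0(L))^2},

with the standard distance scale
:math:`d_0(L) = 1.24 (L-15)^{1/3} - 1.8` floored at 0.5 A.  A score of 1
indicates a perfect match; scores of at least 0.5 conventionally indicate
the same fold.  GDT_TS is the mean, over the 1/2/4/8 A thresholds, of the
fraction of aligned pairs within the threshold, normalized here by the
number of aligned pairs.

Secondary structure is assigned from C-alpha geometry alone: each residue's
state is decided by the six pairwise distances among the five residues
centered on it, against distance patterns characteristic of ideal helices
and strands (the classic CA-distance criteria used by rigid-body aligners).
Residues without a complete five-residue window are coil.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .structure_io import Structure

__all__ = [
    "AlignedPairSet",
    "SubstitutionTable",
    "d0",
    "tm_score",
    "tm_pair_scores",
    "gdt_ts",
    "assign_ss",
    "seq_sim_score",
    "tm_score_2tm",
    "load_substitution_table",
]

GDT_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)

# CA-distance patterns (A) for the five-residue window i-2..i+2; the six
# distances are (d13, d14, d15, d24, d25, d35) with 1-based window indices.
HELIX_PATTERN = ((5.45, 5.18, 6.37, 5.45, 5.18, 5.45), 2.1)
STRAND_PATTERN = ((6.1, 10.4, 13.0, 6.1, 10.4, 6.1), 1.42)


@dataclass
class AlignedPairSet:
    """Sequence-order-preserving aligned residue pairs with distances.

    `q_indices` and `s_indices` are 0-based residue indices, both strictly
    increasing; `distances` are Euclidean separations in A of the paired
    representative atoms after superposition.
    """

    q_indices: np.ndarray
    s_indices: np.ndarray
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.q_indices = np.asarray(self.q_indices, dtype=np.int64)
        self.s_indices = np.asarray(self.s_indices, dtype=np.int64)
        self.distances = np.asarray(self.distances, dtype=float)
        n = self.q_indices.shape[0]
        if self.s_indices.shape[0] != n or self.distances.shape[0] != n:
            raise ValueError("pair arrays must have equal length")
        if n:
            if np.any(np.diff(self.q_indices) <= 0) or np.any(
                np.diff(self.s_indices) <= 0
            ):
                raise ValueError("aligned indices must be strictly increasing")
            if np.any(self.distances < 0):
                raise ValueError("distances must be nonnegative")

    @property
    def n_aligned(self) -> int:
        return int(self.q_indices.shape[0])

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.q_indices.tolist(), self.s_indices.tolist()))

    @staticmethod
    def empty() -> "AlignedPairSet":
        z = np.empty(0)
        return AlignedPairSet(z, z, z)


def d0(L: int) -> float:
    """TM-score distance scale for normalization length `L`, in A.

    ``1.24 * (L - 15)**(1/3) - 1.8`` floored at 0.5 A (the standard
    convention; the cube root is real also for L < 15 where the floor
    applies anyway).
    """
    if L < 1:
        raise ValueError("normalization length must be >= 1")
    if L <= 15:
        return 0.5
    return max(0.5, 1.24 * (L - 15.0) ** (1.0 / 3.0) - 1.8)


def tm_from_distances(distances: np.ndarray, L_norm: int) -> float:
    """TM-score of a distance vector under normalization length `L_norm`."""
    if L_norm < 1:
        raise ValueError("normalization length must be >= 1")
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        return 0.0
    scale = d0(L_norm)
    return float(np.sum(1.0 / (1.0 + (distances / scale) ** 2)) / L_norm)


def tm_score(apairs: AlignedPairSet, L_norm: int) -> float:
    """TM-score of an aligned pair set, normalized by `L_norm`."""
    return tm_from_distances(apairs.distances, L_norm)


def tm_pair_scores(
    apairs: AlignedPairSet, L_q: int, L_s: int
) -> tuple[float, float, float, float]:
    """TM-scores under the three normalizations plus their harmonic mean.

    Returns ``(tm_short, tm_query, tm_subject, harmonic_mean)`` where the
    harmonic mean ``2ab/(a+b)`` combines the query- and subject-normalized
    scores (0 when both vanish); it downweights pairs with large length
    differences and is the default ranking measure for database searches.
    """
    tm_q = tm_from_distances(apairs.distances, L_q)
    tm_s = tm_from_distances(apairs.distances, L_s)
    tm_short = tm_q if L_q <= L_s else tm_s
    denom = tm_q + tm_s
    hmean = 0.0 if denom == 0.0 else 2.0 * tm_q * tm_s / denom
    return tm_short, tm_q, tm_s, hmean


def gdt_ts(apairs: AlignedPairSet) -> float:
    """GDT_TS over the 1/2/4/8 A thresholds, normalized by pair count."""
    if apairs.n_aligned < 1:
        raise ValueError("GDT_TS is undefined for an empty alignment")
    d = apairs.distances
    fracs = [float(np.mean(d <= thr)) for thr in GDT_THRESHOLDS]
    return float(np.mean(fracs))


def _window_state(w: np.ndarray) -> str:
    # w: (5, 3) CA coordinates of residues i-2..i+2
    def dist(i: int, j: int) -> float:
        return float(np.linalg.norm(w[i] - w[j]))

    dvec = (dist(0, 2), dist(0, 3), dist(0, 4), dist(1, 3), dist(1, 4), dist(2, 4))
    for pattern, (targets, delta) in (("H", HELIX_PATTERN), ("E", STRAND_PATTERN)):
        if all(abs(d - t) < delta for d, t in zip(dvec, targets)):
            return pattern
    return "C"


def assign_ss(s: Structure) -> np.ndarray:
    """Per-residue secondary-structure states in {'H', 'E', 'C'}.

    Purely geometric, computed from representative-atom distances over the
    five-residue window centered on each residue; invariant to rigid
    transforms.  Terminal residues with incomplete windows are coil.
    """
    coords = s.repr_coords
    L = coords.shape[0]
    states = np.full(L, "C", dtype="<U1")
    for i in range(2, L - 2):
        states[i] = _window_state(coords[i - 2 : i + 3])
    return states


def local_ss_similarity(ss_a: np.ndarray, ss_b: np.ndarray) -> float:
    """Fraction of positions with identical states between equal-length runs."""
    ss_a = np.asarray(ss_a)
    ss_b = np.asarray(ss_b)
    if ss_a.size == 0:
        return 1.0
    return float(np.mean(ss_a == ss_b))


class SubstitutionTable:
    """Symmetric residue substitution scores loaded from a text asset.

    Scores are accessed by one-letter code; any residue outside the table's
    alphabet (including X) scores 0 against everything.
    """

    def __init__(self, alphabet: str, matrix: np.ndarray):
        if matrix.shape != (len(alphabet), len(alphabet)):
            raise ValueError("matrix shape does not match alphabet")
        if not np.array_equal(matrix, matrix.T):
            raise ValueError("substitution table must be symmetric")
        self.alphabet = alphabet
        self.matrix = matrix.astype(float)
        # dense 26-letter lookup with zero rows for unknowns
        self._lut = np.zeros((27, 27))
        idx = [ord(c) - 65 for c in alphabet]
        for i, a in enumerate(idx):
            for j, b in enumerate(idx):
                self._lut[a, b] = self.matrix[i, j]

    @classmethod
    def from_text(cls, text: str) -> "SubstitutionTable":
        rows: list[list[str]] = [
            line.split()
            for line in text.splitlines()
            if line.strip() and not line.lstrip().startswith("#")
        ]
        alphabet = "".join(rows[0])
        matrix = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
        order = [r[0] for r in rows[1:]]
        if "".join(order) != alphabet:
            raise ValueError("row order does not match alphabet header")
        return cls(alphabet, matrix)

    def score(self, res_a: str, res_b: str) -> float:
        a = ord(res_a.upper()) - 65
        b = ord(res_b.upper()) - 65
        if not (0 <= a < 26 and 0 <= b < 26):
            return 0.0
        return float(self._lut[a, b])

    def encode(self, sequence: str) -> np.ndarray:
        """Map a sequence to lookup codes (26 = out-of-alphabet)."""
        codes = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
        codes = codes.astype(np.int64) - 65
        codes[(codes < 0) | (codes > 25)] = 26
        return codes

    def pair_matrix(self, seq_a: str, seq_b: str) -> np.ndarray:
        """Dense score matrix between two sequences."""
        ca = self.encode(seq_a)
        cb = self.encode(seq_b)
        return self._lut[np.ix_(ca, cb)]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max())


_DEFAULT_TABLE: SubstitutionTable | None = None


def load_substitution_table(path: str | Path | None = None) -> SubstitutionTable:
    """Load a substitution table; the bundled log-odds table by default."""
    global _DEFAULT_TABLE
    if path is not None:
        return SubstitutionTable.from_text(Path(path).read_text())
    if _DEFAULT_TABLE is None:
        text = (
            resources.files("kdalign").joinpath("data/blosum62.txt").read_text()
        )
        _DEFAULT_TABLE = SubstitutionTable.from_text(text)
    return _DEFAULT_TABLE


def seq_sim_score(res_a: str, res_b: str) -> float:
    """Substitution score between two one-letter residue codes."""
    return load_substitution_table().score(res_a, res_b)


def _helix_segments(ss: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of helix state."""
    segs = []
    start = None
    for i, state in enumerate(ss):
        if state == "H" and start is None:
            start = i
        elif state != "H" and start is not None:
            segs.append((start, i))
            start = None
    if start is not None:
        segs.append((start, len(ss)))
    return segs


def filter_unmatched_helices(
    apairs: AlignedPairSet, ss_q: np.ndarray, ss_s: np.ndarray
) -> AlignedPairSet:
    """Drop aligned pairs falling in helices not matched to partner helices.

    A helix segment counts as matched when at least half of its residues are
    aligned to helix-state residues of the partner structure; pairs inside
    unmatched helix segments are excluded on either side.
    """
    ss_q = np.asarray(ss_q)
    ss_s = np.asarray(ss_s)
    if apairs.n_aligned == 0:
        return apairs
    keep = np.ones(apairs.n_aligned, dtype=bool)
    for ss_self, idx_self, ss_other, idx_other in (
        (ss_q, apairs.q_indices, ss_s, apairs.s_indices),
        (ss_s, apairs.s_indices, ss_q, apairs.q_indices),
    ):
        for start, end in _helix_segments(ss_self):
            in_seg = (idx_self >= start) & (idx_self < end)
            n_helix_matched = int(
                np.sum(ss_other[idx_other[in_seg]] == "H")
            )
            if n_helix_matched < 0.5 * (end - start):
                keep &= ~in_seg
    return AlignedPairSet(
        apairs.q_indices[keep], apairs.s_indices[keep], apairs.distances[keep]
    )


def tm_score_2tm(
    apairs: AlignedPairSet,
    ss_q: np.ndarray,
    ss_s: np.ndarray,
    L_norm: int,
) -> float:
    """Secondary TM-score: TM-score excluding unmatched helices.

    Helps fold-level ranking by discounting helices of one structure packed
    against non-helical regions of the other.
    """
    return tm_score(filter_unmatched_helices(apairs, ss_q, ss_s), L_norm)
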