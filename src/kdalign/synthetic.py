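"""Synthetic protein-like fixtures with known ground truth.

Generates C-alpha traces from ideal secondary-structure geometry — helices
with a 2.27 A radius, 1.5 A rise and 100 degrees of turn per residue,
extended two-residue-periodic strands with a 3.5 A step, and persistent
random-walk coils — so that geometric secondary-structure assignment,
superposition recovery and alignment accuracy can all be tested against
construction-time truth without downloading real structures.

Backbone atoms other than the C-alpha are schematic: N, C and O are placed
at fixed local offsets merely so that structures survive backbone-
completeness preprocessing.  Do not use these fixtures for anything that
depends on real backbone geometry; every score in this package consumes
representative (C-alpha) atoms only.

Generation is a pure function of the spec: identical specs (including the
seed) produce byte-identical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Transform, apply_transform, kabsch
from .scoring import AlignedPairSet
from .structure_io import Residue, Structure

__all__ = [
    "SyntheticSpec",
    "make_structure",
    "make_pair",
    "make_decoy_set",
    "random_transform",
    "sample_pair_spec",
]

HELIX_RADIUS = 2.27
HELIX_RISE = 1.5
HELIX_TURN_DEG = 100.0
STRAND_STEP = 3.05
STRAND_OFFSET = 0.8575
COIL_STEP = 3.65

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

# schematic local offsets for the non-representative backbone atoms
_BACKBONE_OFFSETS = {
    "N": np.array([-1.20, 0.60, 0.0]),
    "C": np.array([1.20, 0.60, 0.0]),
    "O": np.array([1.90, 1.40, 0.0]),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic structure (and optionally a derived pair).

    `architecture` lists (state, length) segments with state in
    {"helix", "strand", "coil"}; `indels` lists (position, length, kind)
    edits with kind in {"del", "ins"} applied when deriving the subject of
    a pair; `jitter_sd` is the RMS atomic displacement of the coordinate
    noise in A (isotropic Gaussian with sd/sqrt(3) per coordinate).
    """

    architecture: tuple[tuple[str, int], ...]
    seed: int = 0
    transform: Transform | None = None
    jitter_sd: float = 0.0
    indels: tuple[tuple[int, int, str], ...] = ()
    id: str = "synthetic"

    @property
    def n_residues(self) -> int:
        return sum(n for _, n in self.architecture)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_transform(rng: np.random.Generator, max_shift: float = 20.0) -> Transform:
    """A uniformly random proper rotation with a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-max_shift, max_shift, size=3)
    return Transform(R, t)


def _segment_template(kind: str, n: int, rng: np.random.Generator) -> np.ndarray:
    if kind == "helix":
        i = np.arange(n)
        ang = np.deg2rad(HELIX_TURN_DEG) * i
        return np.stack(
            [HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), HELIX_RISE * i],
            axis=1,
        )
    if kind == "strand":
        i = np.arange(n)
        return np.stack(
            [STRAND_STEP * i, STRAND_OFFSET * (-1.0) ** i, np.zeros(n)], axis=1
        )
    if kind == "coil":
        pts = [np.zeros(3)]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        for _ in range(n - 1):
            direction = direction + 0.9 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pts.append(pts[-1] + COIL_STEP * direction)
        return np.array(pts)
    raise ValueError(f"unknown segment kind {kind!r}")


def _trace_from_architecture(
    architecture, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    coords: list[np.ndarray] = []
    states: list[str] = []
    end = np.zeros(3)
    for kind, n in architecture:
        if n < 1:
            raise ValueError("segment length must be >= 1")
        tpl = _segment_template(kind, n, rng)
        rot = random_transform(rng, max_shift=0.0)
        tpl = apply_transform(tpl - tpl[0], rot)
        if coords:
            step_dir = rng.normal(size=3)
            step_dir /= np.linalg.norm(step_dir)
            tpl = tpl + end + COIL_STEP * step_dir
        coords.append(tpl)
        states.extend({"helix": "H", "strand": "E", "coil": "C"}[kind] for _ in range(n))
        end = tpl[-1]
    return np.concatenate(coords), np.array(states)


def _residues_from_trace(
    ca: np.ndarray, sequence: str, start_number: int = 1
) -> list[Residue]:
    out = []
    for i, (pos, aa) in enumerate(zip(ca, sequence)):
        atoms = {"CA": pos.copy()}
        for name, off in _BACKBONE_OFFSETS.items():
            atoms[name] = pos + off
        out.append(Residue(start_number + i, ONE_TO_THREE[aa], atoms))
    return out


def make_structure(spec: SyntheticSpec) -> tuple[Structure, np.ndarray]:
    """Build a structure from a spec; returns it with ground-truth states."""
    if spec.n_residues < 1:
        raise ValueError("spec must contain at least one residue")
    rng = _rng(spec.seed)
    ca, states = _trace_from_architecture(spec.architecture, rng)
    sequence = "".join(rng.choice(list(AA_ALPHABET), size=len(ca)))
    s = Structure(id=spec.id, residues=_residues_from_trace(ca, sequence))
    return s, states


def _apply_indels(
    coords: np.ndarray,
    sequence: str,
    indels,
    rng: np.random.Generator,
) -> tuple[np.ndarray, str, np.ndarray]:
    """Apply edits; returns coords, sequence and per-output source index
    (-1 for inserted residues)."""
    src = list(range(len(coords)))
    pts = [coords[i] for i in src]
    seq = list(sequence)
    for pos, length, kind in sorted(indels, key=lambda e: -e[0]):
        if kind == "del":
            del pts[pos : pos + length], seq[pos : pos + length], src[pos : pos + length]
        elif kind == "ins":
            anchor = pts[min(pos, len(pts) - 1)]
            walk = _segment_template("coil", length + 1, rng)[1:]
            for k in range(length):
                pts.insert(pos + k, anchor + walk[k])
                seq.insert(pos + k, rng.choice(list(AA_ALPHABET)))
                src.insert(pos + k, -1)
        else:
            raise ValueError(f"unknown indel kind {kind!r}")
    if not pts:
        raise ValueError("indels removed every residue")
    return np.array(pts), "".join(seq), np.array(src, dtype=np.int64)


def make_pair(
    spec: SyntheticSpec,
) -> tuple[Structure, Structure, Transform, AlignedPairSet]:
    """Query, derived subject, true transform and true alignment.

    The subject is the query mapped through the spec's transform (a seeded
    random one when unset) with indels and coordinate jitter applied; the
    true alignment maps every surviving query residue to its subject copy,
    with distances measured under the true transform.
    """
    q, _ = make_structure(spec)
    rng = _rng(spec.seed + 104729)
    transform = spec.transform if spec.transform is not None else random_transform(rng)
    coords, sequence, src = _apply_indels(
        q.repr_coords, q.sequence, spec.indels, rng
    )
    moved = apply_transform(coords, transform)
    if spec.jitter_sd > 0:
        # jitter_sd is the RMS atomic displacement; isotropic Gaussian noise
        # therefore uses sd/sqrt(3) per coordinate
        moved = moved + rng.normal(
            scale=spec.jitter_sd / np.sqrt(3.0), size=moved.shape
        )
    s = Structure(
        id=spec.id + "_subject",
        residues=_residues_from_trace(moved, sequence),
    )
    s_pos = np.flatnonzero(src >= 0)
    q_pos = src[s_pos]
    keep = np.ones(s_pos.size, dtype=bool)  # deletions keep q order increasing
    d = np.linalg.norm(
        apply_transform(q.repr_coords[q_pos], transform) - s.repr_coords[s_pos],
        axis=1,
    )
    truth = AlignedPairSet(q_pos[keep], s_pos[keep], d[keep])
    return q, s, transform, truth


def sample_pair_spec(
    seed: int,
    min_len: int = 60,
    max_len: int = 140,
    indel_frac: float = 0.2,
    jitter_sd: float = 0.5,
    id: str = "pair",
) -> SyntheticSpec:
    """A randomized mixed-architecture pair spec at the study conditions.

    Lengths are protein-domain-like; up to `indel_frac` of the residues are
    deleted or inserted in a few contiguous blocks and coordinates carry
    coordinate noise with an RMS atomic displacement of `jitter_sd` A.
    """
    rng = _rng(seed)
    L = int(rng.integers(min_len, max_len + 1))
    arch: list[tuple[str, int]] = []
    remaining = L
    while remaining > 0:
        kind = rng.choice(["helix", "strand", "coil"], p=[0.45, 0.3, 0.25])
        n = int(min(remaining, rng.integers(6, 18)))
        arch.append((str(kind), n))
        remaining -= n
    n_edit = int(indel_frac * L)
    indels: list[tuple[int, int, str]] = []
    while n_edit > 0:
        length = int(min(n_edit, rng.integers(1, 8)))
        pos = int(rng.integers(0, max(1, L - length)))
        kind = "del" if rng.random() < 0.5 else "ins"
        indels.append((pos, length, kind))
        n_edit -= length
    return SyntheticSpec(
        architecture=tuple(arch),
        seed=seed,
        jitter_sd=jitter_sd,
        indels=tuple(indels),
        id=f"{id}{seed}",
    )


def make_decoy_set(
    n: int,
    seed: int,
    length: int = 60,
    tm_limit: float = 0.4,
    budget: int = 60,
) -> list[Structure]:
    """Structures certified mutually dissimilar (pairwise TM below limit).

    Coil-walk structures are rejection-sampled; certification runs the
    package's own aligner at its most thorough setting, so the guarantee is
    with respect to the same scoring used everywhere else.
    """
    from .engine import SearchParams, align_pair  # deferred: avoid cycle

    params = SearchParams(speed=0)
    decoys: list[Structure] = []
    attempt = 0
    sub_seed = seed
    while len(decoys) < n:
        if attempt >= budget:
            raise RuntimeError(
                f"decoy rejection budget ({budget}) exhausted at {len(decoys)}/{n}"
            )
        attempt += 1
        sub_seed += 1
        spec = SyntheticSpec(
            architecture=(("coil", length),),
            seed=seed * 7919 + sub_seed,
            id=f"decoy{len(decoys)}",
        )
        cand, _ = make_structure(spec)
        ok = all(
            align_pair(cand, other, params).alignment.tm_short < tm_limit
            for other in decoys
        )
        if ok:
            decoys.append(cand)
    return decoys
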