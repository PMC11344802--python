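"""Rigid-body mathematics and spatial indexing.

Superpositions are represented as proper rotations plus translations
(:class:`Transform`).  The optimal least-RMSD superposition of paired point
sets is computed with the Kabsch algorithm, either in full double precision
or in a single-precision mode that first normalizes the cross-covariance
matrix by the mean magnitude of its elements.  The normalization amounts to
a uniform rescaling of the coordinates (Angstroms to roughly nanometers for
large proteins), which keeps the 3x3 eigenproblem well inside the dynamic
range of 32-bit floats; the scale factor cancels in the rotation.

Nearest-neighbor queries over a structure's representative atoms go through
an exact k-d tree (:class:`SpatialIndex`).  Ties are broken toward the
smaller residue index so that queries are deterministic across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Transform",
    "SpatialIndex",
    "kabsch",
    "apply_transform",
    "rmsd",
    "build_index",
    "nearest_within",
]

#: tolerance used when two neighbors are considered equidistant
_TIE_EPS = 1e-9


@dataclass(frozen=True)
class Transform:
    """A rigid-body map ``x -> R @ x + t``.

    Attributes
    ----------
    R : (3, 3) ndarray
        Proper rotation matrix (orthogonal, determinant +1).
    t : (3,) ndarray
        Translation in Angstroms.
    degenerate : bool
        Set when the point sets the transform was fitted to were rank
        deficient (collinear or coincident); the rotation is still a valid
        proper rotation but is not uniquely determined by the data.
    """

    R: np.ndarray
    t: np.ndarray
    degenerate: bool = False

    @staticmethod
    def identity() -> "Transform":
        return Transform(np.eye(3), np.zeros(3))

    def compose(self, other: "Transform") -> "Transform":
        """Return the transform equivalent to applying `other` then `self`."""
        return Transform(self.R @ other.R, self.R @ other.t + self.t)

    def inverse(self) -> "Transform":
        Rinv = self.R.T
        return Transform(Rinv, -Rinv @ self.t)

    def is_proper(self, tol: float = 1e-6) -> bool:
        return (
            np.max(np.abs(self.R.T @ self.R - np.eye(3))) < tol
            and abs(np.linalg.det(self.R) - 1.0) < tol
        )


def apply_transform(coords: np.ndarray, t: Transform) -> np.ndarray:
    """Apply ``x -> R x + t`` row-wise to an (N, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    return coords @ t.R.T + t.t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between paired coordinate rows, in A."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"paired sets differ in shape: {a.shape} vs {b.shape}")
    if a.shape[0] < 1:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _rotation_from_covariance(K: np.ndarray) -> tuple[np.ndarray, bool]:
    """Proper rotation from a 3x3 cross-covariance matrix, double precision.

    Uses the SVD formulation with the determinant sign fix; returns the
    rotation and a degeneracy flag (rank < 2 leaves the rotation
    underdetermined).
    """
    U, S, Vt = np.linalg.svd(K)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    degenerate = bool(S[1] <= 1e-8 * max(S[0], 1.0))
    return R, degenerate


def _eig3_closed_fp32(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form eigen-solution of a symmetric 3x3 in single precision.

    Eigenvalues from the trigonometric solution of the characteristic
    cubic; eigenvectors of the two largest from cross products of rows of
    ``S - mu I`` (the largest-norm cross), the third completing the basis.
    This mirrors what accelerator kernels use instead of a LAPACK solver
    and carries the characteristic single-precision error.
    """
    f32 = np.float32
    q = f32(np.trace(S) / 3)
    p1 = f32(S[0, 1] ** 2 + S[0, 2] ** 2 + S[1, 2] ** 2)
    p2 = f32((S[0, 0] - q) ** 2 + (S[1, 1] - q) ** 2 + (S[2, 2] - q) ** 2 + 2 * p1)
    p = f32(np.sqrt(p2 / f32(6)))
    if p == 0:  # S is a multiple of the identity
        return np.array([q, q, q], dtype=f32), np.eye(3, dtype=f32)
    B = ((S - q * np.eye(3, dtype=f32)) / p).astype(f32)
    r = f32(np.linalg.det(B) / 2)
    r = min(max(r, f32(-1)), f32(1))
    phi = f32(np.arccos(r) / 3)
    e1 = f32(q + 2 * p * np.cos(phi))
    e3 = f32(q + 2 * p * np.cos(phi + f32(2 * np.pi / 3)))
    e2 = f32(3 * q - e1 - e3)
    eigs = np.array([e1, e2, e3], dtype=f32)
    vecs = []
    for mu in eigs[:2]:
        M = (S - mu * np.eye(3, dtype=f32)).astype(f32)
        cands = [np.cross(M[0], M[1]), np.cross(M[0], M[2]), np.cross(M[1], M[2])]
        norms = [np.linalg.norm(c) for c in cands]
        v = cands[int(np.argmax(norms))]
        n = f32(norms[int(np.argmax(norms))])
        vecs.append((v / n).astype(f32) if n > 0 else np.eye(3, dtype=f32)[len(vecs)])
    v2 = np.cross(vecs[0], vecs[1]).astype(f32)
    return eigs, np.stack([vecs[0], vecs[1], v2], axis=1)


def _rotation_fp32_normalized(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Rotation via the normalized single-precision Kabsch pipeline.

    Coordinates are cast to float32, the cross-covariance matrix K is
    accumulated in float32 and divided by the mean of the absolute values
    of its elements (equivalent to rescaling the atom coordinates, which
    keeps large proteins inside the float32 dynamic range; the scale
    cancels in the rotation), and the eigenproblem of K^T K is solved in
    closed form in float32.  Falls back to the double route for rank-
    deficient inputs.
    """
    f32 = np.float32
    a32 = a.astype(f32)
    b32 = b.astype(f32)
    K = (a32 - a32.mean(axis=0)).T @ (b32 - b32.mean(axis=0))
    scale = f32(np.mean(np.abs(K)))
    if not scale > 0:
        return np.eye(3), True
    K = (K / scale).astype(f32)
    S = (K.T @ K).astype(f32)
    eigs, A = _eig3_closed_fp32(S)
    if eigs[1] <= 1e-6 * max(float(eigs[0]), 1.0):
        R, _ = _rotation_from_covariance(a.T @ b)  # degenerate: double fallback
        return R, True
    b0 = (K @ A[:, 0]).astype(f32) / f32(np.sqrt(max(eigs[0], f32(1e-20))))
    b1 = (K @ A[:, 1]).astype(f32) / f32(np.sqrt(max(eigs[1], f32(1e-20))))
    b2 = np.cross(b0, b1).astype(f32)
    B = np.stack([b0, b1, b2], axis=1)
    return (B @ A.T).astype(np.float64), False


def kabsch(
    a: np.ndarray,
    b: np.ndarray,
    precision_mode: str = "double",
) -> Transform:
    """Least-RMSD proper rotation + translation mapping `b` onto `a`.

    Parameters
    ----------
    a, b : (N, 3) arrays
        Paired coordinates; the returned transform minimizes
        ``RMSD(a, R b + t)`` over proper rotations.
    precision_mode : {"double", "fp32_normalized"}
        ``double`` solves the 3x3 problem in full double precision via SVD.
        ``fp32_normalized`` first divides the cross-covariance matrix by the
        mean of the absolute values of its elements and then solves the
        eigenproblem in 32-bit floats; the rotation is used as-is (the
        scaling cancels), while the translation is always accumulated in
        double precision.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("kabsch expects two equally shaped (N, 3) arrays")
    n = a.shape[0]
    if n < 3:
        raise ValueError(f"kabsch is underdetermined for N={n} < 3 pairs")
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    K = (a - ca).T @ (b - cb)
    if precision_mode == "double":
        R, degenerate = _rotation_from_covariance(K)
    elif precision_mode == "fp32_normalized":
        R, degenerate = _rotation_fp32_normalized(a - ca, b - cb)
    else:
        raise ValueError(f"unknown precision_mode: {precision_mode!r}")
    if not np.all(np.abs(K) > 0) and np.allclose(K, 0.0):
        # coincident point clouds: rotation is arbitrary, report identity
        R, degenerate = np.eye(3), True
    t = ca - R @ cb
    return Transform(R, t, degenerate=degenerate)


@dataclass
class SpatialIndex:
    """Exact k-d tree over one structure's representative coordinates."""

    tree: cKDTree
    coords: np.ndarray = field(repr=False)

    @property
    def owner_length(self) -> int:
        return self.coords.shape[0]


def build_index(coords_or_structure) -> SpatialIndex:
    """Build a spatial index over representative atom coordinates.

    Accepts an (L, 3) array or any object with a ``repr_coords`` attribute
    (a parsed structure).  Queries against the index return exact nearest
    neighbors; equidistant candidates resolve to the smaller residue index.
    """
    coords = getattr(coords_or_structure, "repr_coords", coords_or_structure)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
        raise ValueError("spatial index requires a non-empty (L, 3) array")
    return SpatialIndex(tree=cKDTree(coords), coords=coords)


def nearest_within(
    idx: SpatialIndex, point: np.ndarray, cutoff: float
) -> tuple[int, float] | None:
    """Nearest residue to `point` if within `cutoff` A, else ``None``."""
    res = query_nearest(idx, np.asarray(point, dtype=float)[None, :], cutoff)
    i, d = int(res[0][0]), float(res[1][0])
    if i < 0:
        return None
    return i, d


def query_nearest(
    idx: SpatialIndex, points: np.ndarray, cutoff: float = np.inf
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized nearest-residue lookup for a batch of points.

    Returns ``(indices, distances)``; residues farther than `cutoff` yield
    index -1 and distance ``inf``.  Two nearest neighbors are retrieved per
    point so that exact ties resolve to the smaller index.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    k = min(2, idx.owner_length)
    dist, ind = idx.tree.query(points, k=k)
    if k == 1:
        dist = dist[:, None]
        ind = ind[:, None]
    best_i = ind[:, 0].astype(np.int64)
    best_d = dist[:, 0]
    if k == 2:
        tied = np.abs(dist[:, 1] - dist[:, 0]) <= _TIE_EPS
        lower = ind[:, 1] < ind[:, 0]
        swap = tied & lower
        best_i[swap] = ind[swap, 1]
        best_d[swap] = dist[swap, 1]
    out = best_d <= cutoff
    best_i = np.where(out, best_i, -1)
    best_d = np.where(out, best_d, np.inf)
    return best_i, best_d
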