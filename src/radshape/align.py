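"""Rigid registration (ICP) and generalized Procrustes alignment.

All specimens are brought into one standardized frame: meshes are registered
rigidly to a reference specimen (point-to-point ICP with Kabsch updates),
and corresponded landmark sets are aligned to their evolving mean by
generalized Procrustes analysis.  Scale is retained by default so that
size-bearing analyses (gender differences, absolute morphometrics) remain
meaningful; an optional similarity mode removes it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "RigidTransform",
    "kabsch",
    "rigid_icp",
    "principal_axes_init",
    "generalized_procrustes",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[:3, :3], m[:3, 3])

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()


def _superpose(src: np.ndarray, tgt: np.ndarray,
               allow_scaling: bool) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal (scaled) rotation + translation; returns (linear map M, t, rms)."""
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    A, B = src - mu_s, tgt - mu_t
    U, S, Vt = np.linalg.svd(A.T @ B)
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(Vt.T @ U.T))
    M = Vt.T @ D @ U.T
    if allow_scaling:
        denom = (A * A).sum()
        scale = (S * np.diag(D)).sum() / denom if denom > 0 else 1.0
        M = M * scale
    t = mu_t - M @ mu_s
    moved = src @ M.T + t
    rms = float(np.sqrt(((moved - tgt) ** 2).sum(axis=1).mean()))
    return M, t, rms


def kabsch(source: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of paired point sets (Kabsch/SVD).

    Returns the transform mapping ``source`` onto ``target`` and the RMS
    residual after alignment.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape:
        raise ValueError("paired point sets must have identical shapes")
    M, t, rms = _superpose(src, tgt, allow_scaling=False)
    return RigidTransform(M, t), rms


def principal_axes_init(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Coarse initialization aligning centroids and principal axes.

    The 180-degree ambiguities are resolved by third-moment skew along the
    longest axis (the styloid apex makes the distal direction heavy-tailed)
    and along the shortest cross-section axis (the dorsal tubercle skews the
    dorso-volar direction); the remaining axis completes a right-handed
    frame.  Mirror-image specimens therefore keep dorsal dorsal and distal
    distal instead of being spun half a turn to chase the lateral feature.
    """
    def frame(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu = pts.mean(axis=0)
        centered = pts - mu
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        long_axis, mid_axis, short_axis = vt[0], vt[1], vt[2]
        if np.mean((centered @ long_axis) ** 3) < 0:
            long_axis = -long_axis
        if np.mean((centered @ short_axis) ** 3) < 0:
            short_axis = -short_axis
        mid_axis = np.cross(short_axis, long_axis)
        axes = np.vstack([long_axis, mid_axis, short_axis])
        return mu, axes

    mu_s, ax_s = frame(np.asarray(source_points, float))
    mu_t, ax_t = frame(np.asarray(target_points, float))
    R = ax_t.T @ ax_s
    return RigidTransform(R, mu_t - R @ mu_s)


def rigid_icp(
    source,
    target,
    init: RigidTransform | None = None,
    max_iter: int = 200,
    tol: float = 1e-10,
    sample: int | None = 4000,
    rng: np.random.Generator | None = None,
) -> tuple[RigidTransform, float, np.ndarray]:
    """ICP registering ``source`` into the ``target`` frame.

    ``source`` may be a mesh or an (n, 3) point set.  When ``target`` is a
    mesh, correspondences are the closest points on its surface (any point of
    any triangle), which avoids the discretization plateaus of nearest-vertex
    matching; for a point-set target the nearest point is used.  At most
    ``sample`` source points participate (deterministic subsample).  Returns
    ``(transform, final_rms, rms_history)``; the RMS sequence is
    non-increasing by construction of the alternating minimization.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    src = source.vertices if isinstance(source, trimesh.Trimesh) else np.asarray(source, float)
    target_mesh = target if isinstance(target, trimesh.Trimesh) else None
    tgt = target.vertices if target_mesh is not None else np.asarray(target, float)
    if src.size == 0 or tgt.size == 0:
        raise ValueError("empty input")
    if not (np.isfinite(src).all() and np.isfinite(tgt).all()):
        raise ValueError("non-finite coordinates")
    if sample is not None and len(src) > sample:
        idx = (np.random.default_rng(0) if rng is None else rng).choice(
            len(src), sample, replace=False
        )
        src = src[np.sort(idx)]
    xf = init if init is not None else RigidTransform.identity()
    tree = None if target_mesh is not None else cKDTree(tgt)

    def correspond(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if target_mesh is not None:
            from ._geometry import closest_point_on_mesh

            cp, dist, _ = closest_point_on_mesh(target_mesh, points, k=8)
            return cp, dist
        dist, nn = tree.query(points)
        return tgt[nn], dist

    history: list[float] = []
    moved = xf.apply(src)
    for _ in range(max_iter):
        matched, dist = correspond(moved)
        history.append(float(np.sqrt((dist**2).mean())))
        step, _ = kabsch(moved, matched)
        xf = step.compose(xf)
        moved = xf.apply(src)
        new_rms = float(np.sqrt(((moved - matched) ** 2).sum(axis=1).mean()))
        if history[-1] - new_rms < tol:
            break
    _, dist = correspond(moved)
    final = float(np.sqrt((dist**2).mean()))
    history.append(final)
    return xf, final, np.asarray(history)


def generalized_procrustes(
    shapes: list[np.ndarray],
    allow_scaling: bool = False,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Generalized Procrustes alignment of corresponded landmark sets.

    Iterates optimal superposition of every shape onto the evolving mean
    until the mean moves by less than ``tol``.  With ``allow_scaling=False``
    (default) each shape keeps its centroid size exactly.  Returns
    ``(aligned shapes in input order, mean shape, per-shape RMS residuals)``.
    """
    if len(shapes) < 2:
        raise ValueError("need at least two shapes")
    arrs = [np.asarray(s, dtype=float) for s in shapes]
    n = arrs[0].shape
    if any(a.shape != n for a in arrs):
        raise ValueError("mismatched landmark counts across shapes")

    aligned = [a - a.mean(axis=0) for a in arrs]
    mean = aligned[0].copy()
    ref_size = np.linalg.norm(mean)
    for _ in range(max_iter):
        new_aligned = []
        for a in aligned:
            M, t, _ = _superpose(a, mean, allow_scaling=allow_scaling)
            new_aligned.append(a @ M.T + t)
        new_mean = np.mean(new_aligned, axis=0)
        if allow_scaling:
            # pin the similarity gauge: keep the mean at constant centroid size
            norm = np.linalg.norm(new_mean - new_mean.mean(axis=0))
            if norm > 0:
                new_mean = (new_mean - new_mean.mean(axis=0)) * (ref_size / norm)
        shift = float(np.linalg.norm(new_mean - mean) / np.sqrt(new_mean.size))
        aligned = new_aligned
        mean = new_mean
        if shift < tol:
            break
    residuals = np.array([
        float(np.sqrt(((a - mean) ** 2).sum(axis=1).mean())) for a in aligned
    ])
    return aligned, mean, residuals
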