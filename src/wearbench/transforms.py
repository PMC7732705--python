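"""Rigid-body transforms in homogeneous coordinates.

All geometry in this package lives in millimetres; a :class:`RigidTransform`
maps follow-up scan coordinates into the baseline frame.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform"]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion stored as a 4x4 homogeneous matrix.

    Invariants (checked on construction): the rotation block is orthonormal
    to 1e-9, has determinant +1, and the last matrix row is (0, 0, 0, 1).
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got shape {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("transform matrix contains non-finite entries")
        r = m[:3, :3]
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation block is a reflection (det < 0)")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=_ORTHO_TOL):
            raise ValueError("last row must be (0, 0, 0, 1)")
        object.__setattr__(self, "matrix", m)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(rotation, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m)

    @classmethod
    def from_axis_angle(
        cls, axis: np.ndarray, angle_deg: float, translation: np.ndarray | None = None
    ) -> "RigidTransform":
        """Rodrigues rotation about ``axis`` (need not be unit) plus a shift."""
        axis = np.asarray(axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("rotation axis must be nonzero")
        k = axis / norm
        theta = np.deg2rad(angle_deg)
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        r = np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        return cls.from_rotation_translation(r, t)

    # -- accessors ---------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        tr = np.trace(self.rotation)
        c = np.clip((tr - 1.0) / 2.0, -1.0, 1.0)
        return float(np.rad2deg(np.arccos(c)))

    # -- algebra -----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array of points (or a single 3-vector)."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        v = np.asarray(vectors, dtype=float)
        single = v.ndim == 1
        v = np.atleast_2d(v)
        out = v @ self.rotation.T
        return out[0] if single else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self @ other`` (apply ``other`` first, then ``self``)."""
        return RigidTransform(self.matrix @ other.matrix)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        r = self.rotation.T
        return RigidTransform.from_rotation_translation(r, -r @ self.translation)

    def almost_equal(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=atol))

    def as_flat12(self) -> np.ndarray:
        """Top 3 rows, row-major (12 floats) — the on-disk representation."""
        return self.matrix[:3, :].reshape(-1).copy()

    @classmethod
    def from_flat12(cls, values) -> "RigidTransform":
        vals = np.asarray(values, dtype=float).reshape(3, 4)
        m = np.eye(4)
        m[:3, :] = vals
        return cls(m)


def orthonormalize(rotation: np.ndarray) -> np.ndarray:
    """Project a near-rotation matrix onto SO(3) via SVD (polar decomposition)."""
    u, _, vt = np.linalg.svd(np.asarray(rotation, dtype=float))
    r = u @ vt
    if np.linalg.det(r) < 0:
        u = u.copy()
        u[:, -1] *= -1
        r = u @ vt
    return r
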