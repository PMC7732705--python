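"""Core surface data types: labeled triangle meshes, raster height grids, planes."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "REGIONS",
    "REGION_CODES",
    "SurfaceScan",
    "RasterGrid",
    "Plane",
    "ValidationError",
]

#: Canonical region vocabulary. Codes are the on-disk PLY encoding.
REGIONS = ("other", "occlusal", "buccal", "lingual")
REGION_CODES = {name: i for i, name in enumerate(REGIONS)}

_DEGENERATE_AREA_MM2 = 1e-12


class ValidationError(ValueError):
    """Raised when a scan, grid, or label table violates its contract."""


@dataclass
class SurfaceScan:
    """A labeled triangle mesh of one tooth at one timepoint (coordinates in mm).

    Parameters
    ----------
    vertices : (n, 3) float array, mm.
    faces : (m, 3) int array of vertex indices (counter-clockwise when viewed
        from outside).
    region_labels : (n,) array of strings drawn from :data:`REGIONS`.
    provenance : free-form metadata; conventional keys are ``capture_model``
        (``profilometer`` | ``intraoral`` | ``ideal``), ``timepoint``
        (``baseline`` | ``followup``) and ``seed``.

    Construction drops exactly-degenerate (zero-area) faces and validates
    index bounds, label length and finiteness.
    """

    vertices: np.ndarray
    faces: np.ndarray
    region_labels: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValidationError(f"vertices must be (n, 3); got {v.shape}")
        if f.size == 0:
            f = f.reshape(0, 3)
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValidationError(f"faces must be (m, 3); got {f.shape}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("vertex coordinates must be finite")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValidationError("face indices out of range")
        if self.region_labels is None:
            labels = np.full(len(v), "other", dtype="<U8")
        else:
            labels = np.asarray(self.region_labels, dtype="<U8")
            if labels.shape != (len(v),):
                raise ValidationError(
                    f"region_labels length {labels.shape} does not match {len(v)} vertices"
                )
            bad = set(np.unique(labels)) - set(REGIONS)
            if bad:
                raise ValidationError(f"unknown region labels: {sorted(bad)}")
        if f.size:
            # drop zero-area faces (repeated indices or exactly collinear corners)
            a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
            areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
            keep = areas > _DEGENERATE_AREA_MM2
            f = f[keep]
        self.vertices = v
        self.faces = f
        self.region_labels = labels

    # -- basic quantities --------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangle_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        f = self.faces
        v = self.vertices
        return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]

    def face_normals(self, normalized: bool = True) -> np.ndarray:
        a, b, c = self.triangle_corners()
        n = np.cross(b - a, c - a)
        if normalized:
            norms = np.linalg.norm(n, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            n = n / norms
        return n

    def face_areas(self) -> np.ndarray:
        a, b, c = self.triangle_corners()
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def edges(self) -> np.ndarray:
        """Unique undirected edges, (e, 2) with sorted index pairs."""
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def is_manifold_with_boundary(self) -> bool:
        """True when every edge borders one or two faces and the mesh is connected."""
        f = self.faces
        if len(f) == 0:
            return False
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        if counts.max() > 2:
            return False
        # connectivity over the face graph via union of vertex components
        import scipy.sparse as sp
        from scipy.sparse.csgraph import connected_components

        used = np.unique(f)
        n = self.n_vertices
        rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
        cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
        adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        n_comp, labels = connected_components(adj, directed=False)
        return len(np.unique(labels[used])) == 1

    def copy(self) -> "SurfaceScan":
        return SurfaceScan(
            self.vertices.copy(),
            self.faces.copy(),
            self.region_labels.copy(),
            dict(self.provenance),
        )

    def transformed(self, transform) -> "SurfaceScan":
        """Return a copy with vertices moved by a RigidTransform."""
        return SurfaceScan(
            transform.apply(self.vertices),
            self.faces.copy(),
            self.region_labels.copy(),
            dict(self.provenance),
        )

    def region_mask(self, labels) -> np.ndarray:
        labels = {labels} if isinstance(labels, str) else set(labels)
        return np.isin(self.region_labels, sorted(labels))


@dataclass
class RasterGrid:
    """Single-valued height grid: one z per (x, y) node; NaN marks missing cells.

    ``x_step_um``/``y_step_um`` are the raster spacings in micrometres;
    ``heights`` is in mm, indexed ``heights[iy, ix]``. Being single-valued is
    what makes a raster capture blind to undercuts.
    """

    x_step_um: float
    y_step_um: float
    heights: np.ndarray
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.x_step_um <= 0 or self.y_step_um <= 0:
            raise ValidationError("grid steps must be positive")
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 2:
            raise ValidationError("heights must be a 2D array")
        self.heights = h

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def node_xy_mm(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.heights.shape
        x = self.origin_mm[0] + np.arange(nx) * self.x_step_um * 1e-3
        y = self.origin_mm[1] + np.arange(ny) * self.y_step_um * 1e-3
        return x, y

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.heights)


@dataclass(frozen=True)
class Plane:
    """Plane {x : x . normal = offset} with unit normal; offset in mm."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm == 0:
            raise ValidationError("plane normal must be nonzero and finite")
        # normalizing the normal rescales the offset so the point set is unchanged
        object.__setattr__(self, "normal", n / norm)
        object.__setattr__(self, "offset", float(self.offset) / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = pts @ self.normal - self.offset
        return d[0] if np.asarray(points).ndim == 1 else d

    def project(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        d = self.signed_distance(pts)
        return pts - np.multiply.outer(d, self.normal)

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two orthonormal in-plane directions (deterministic)."""
        n = self.normal
        ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(n, ref)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v
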