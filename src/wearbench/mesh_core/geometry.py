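"""Geometric primitives: grid triangulation, normals, submeshes, plane fits."""
from __future__ import annotations

import numpy as np

from .types import Plane, RasterGrid, SurfaceScan, ValidationError

__all__ = ["grid_to_scan", "vertex_normals", "region_submesh", "fit_plane"]


def grid_to_scan(grid: RasterGrid) -> SurfaceScan:
    """Triangulate a raster height grid into a SurfaceScan.

    Each grid quad with 4 valid (finite) corners becomes two triangles; quads
    touching any missing cell are skipped entirely — missing raster data is
    dropped, never interpolated. Triangles are wound so normals point +z for
    an upward-facing height field.
    """
    h = grid.heights
    ny, nx = h.shape
    valid = grid.valid_mask()
    if valid.sum() < 4 or ny < 2 or nx < 2:
        raise ValidationError("grid needs at least a 2x2 block of valid cells")
    x, y = grid.node_xy_mm()
    xx, yy = np.meshgrid(x, y)
    verts = np.column_stack([xx.ravel(), yy.ravel(), h.ravel()])
    idx = np.arange(ny * nx).reshape(ny, nx)

    q00 = idx[:-1, :-1].ravel()
    q10 = idx[:-1, 1:].ravel()
    q01 = idx[1:, :-1].ravel()
    q11 = idx[1:, 1:].ravel()
    quad_ok = (
        valid[:-1, :-1] & valid[:-1, 1:] & valid[1:, :-1] & valid[1:, 1:]
    ).ravel()
    if not quad_ok.any():
        raise ValidationError("no quad has 4 valid corners")
    t1 = np.column_stack([q00, q10, q11])[quad_ok]
    t2 = np.column_stack([q00, q11, q01])[quad_ok]
    faces = np.concatenate([t1, t2])

    # compact: keep only referenced vertices (drops isolated/missing nodes)
    used = np.unique(faces)
    remap = np.full(len(verts), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    if not np.all(np.isfinite(verts[used])):
        raise ValidationError("valid-cell bookkeeping failed (non-finite vertex kept)")
    return SurfaceScan(verts[used], remap[faces])


def vertex_normals(scan: SurfaceScan) -> np.ndarray:
    """Area-weighted per-vertex unit normals.

    Isolated vertices (no incident face) get a zero normal — callers that
    care should check for rows with zero norm.
    """
    fn = scan.face_normals(normalized=False)  # length = 2 * area, encodes weighting
    normals = np.zeros_like(scan.vertices)
    for k in range(3):
        np.add.at(normals, scan.faces[:, k], fn)
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    nz = norms[:, 0] > 0
    normals[nz] /= norms[nz]
    return normals


def region_submesh(scan: SurfaceScan, labels) -> tuple[SurfaceScan, np.ndarray]:
    """Extract the faces whose three vertices all carry a requested label.

    Returns ``(submesh, index_map)`` where ``index_map[i]`` is the parent
    vertex index of submesh vertex ``i`` (injective by construction).
    """
    labels = {labels} if isinstance(labels, str) else set(labels)
    if not labels:
        raise ValidationError("label set must be nonempty")
    vmask = scan.region_mask(labels)
    fmask = vmask[scan.faces].all(axis=1)
    faces = scan.faces[fmask]
    if len(faces) == 0:
        raise ValidationError(f"no faces lie entirely within regions {sorted(labels)}")
    used = np.unique(faces)
    remap = np.full(scan.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub = SurfaceScan(
        scan.vertices[used],
        remap[faces],
        scan.region_labels[used],
        dict(scan.provenance),
    )
    return sub, used


def fit_plane(points: np.ndarray, orient_along: np.ndarray | None = None) -> Plane:
    """Total-least-squares plane through a point set (smallest singular vector).

    ``orient_along``: optional vector the normal's sign is matched to
    (typically the mean vertex normal of the region).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValidationError("need at least 3 points of shape (n, 3)")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear input: second singular value vanishes relative to the first
    if s[0] <= 0 or s[1] <= max(s[0] * 1e-10, 1e-14):
        raise ValidationError("points are collinear or degenerate; plane is undefined")
    normal = vt[2]
    if orient_along is not None and np.dot(normal, np.asarray(orient_along, dtype=float)) < 0:
        normal = -normal
    return Plane(normal, float(np.dot(normal, centroid)))
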