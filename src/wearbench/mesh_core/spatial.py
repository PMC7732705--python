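"""Exact closest-point and ray queries against a triangle set.

Queries are accelerated with a vertex KD-tree (closest point) and a projected
2D KD-tree (rays) but return results identical to brute force over all
triangles; ties are broken toward the lowest face index so every query is
deterministic.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .types import SurfaceScan, ValidationError

__all__ = ["TriangleSoup", "closest_point", "ray_intersect", "ray_hit_count"]

_EPS = 1e-12


def _closest_point_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Closest point on triangle (a, b, c) to p, all (k, 3); vectorized Ericson."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex region A
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    # vertex region B
    m = ~done & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    # vertex region C
    m = ~done & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m
    # edge AB
    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1 - d3
    t = np.where(np.abs(denom) > _EPS, d1 / np.where(denom == 0, 1.0, denom), 0.0)
    out[m] = a[m] + t[m, None] * ab[m]
    done |= m
    # edge AC
    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2 - d6
    t = np.where(np.abs(denom) > _EPS, d2 / np.where(denom == 0, 1.0, denom), 0.0)
    out[m] = a[m] + t[m, None] * ac[m]
    done |= m
    # edge BC
    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    t = np.where(np.abs(denom) > _EPS, (d4 - d3) / np.where(denom == 0, 1.0, denom), 0.0)
    out[m] = b[m] + t[m, None] * (c[m] - b[m])
    done |= m
    # interior
    m = ~done
    denom = va + vb + vc
    denom = np.where(np.abs(denom) < _EPS, 1.0, denom)
    v = vb / denom
    w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


class TriangleSoup:
    """Accelerated, exact query structure over a mesh's triangles."""

    def __init__(self, scan: SurfaceScan):
        if scan.n_faces == 0:
            raise ValidationError("cannot build spatial queries on an empty mesh")
        self.scan = scan
        self.a, self.b, self.c = scan.triangle_corners()
        self.face_normals = scan.face_normals()
        # CSR vertex -> incident faces
        f = scan.faces
        flat = f.reshape(-1)
        order = np.argsort(flat, kind="stable")
        self._inc_faces = order // 3
        counts = np.bincount(flat, minlength=scan.n_vertices)
        self._inc_ptr = np.concatenate([[0], np.cumsum(counts)])

        # per-face max edge length, and per-vertex max over incident faces;
        # used to bound how far a candidate face's nearest vertex can be from
        # the true closest point
        edge_len = np.stack(
            [
                np.linalg.norm(self.b - self.a, axis=1),
                np.linalg.norm(self.c - self.b, axis=1),
                np.linalg.norm(self.a - self.c, axis=1),
            ]
        )
        face_max_edge = edge_len.max(axis=0)
        self._centroids = (self.a + self.b + self.c) / 3.0
        self._face_radius = np.sqrt(
            np.maximum.reduce(
                [
                    np.einsum("ij,ij->i", self.a - self._centroids, self.a - self._centroids),
                    np.einsum("ij,ij->i", self.b - self._centroids, self.b - self._centroids),
                    np.einsum("ij,ij->i", self.c - self._centroids, self.c - self._centroids),
                ]
            )
        )
        m_v = np.zeros(scan.n_vertices)
        for k in range(3):
            np.maximum.at(m_v, f[:, k], face_max_edge)
        self._used = np.flatnonzero(counts > 0)
        self._vtree = cKDTree(scan.vertices[self._used])

        # bucket face-bearing vertices into log2 classes of m_v so candidate
        # search radii adapt to local triangle size
        mu = m_v[self._used]
        lo = max(mu[mu > 0].min(), 1e-12)
        cls = np.clip(np.ceil(np.log2(np.maximum(mu, lo) / lo)), 0, 40).astype(int)
        self._classes = []
        for c in np.unique(cls):
            members = self._used[cls == c]
            self._classes.append((float(mu[cls == c].max()), members, cKDTree(scan.vertices[members])))

    def _expand_faces(self, qi: np.ndarray, vi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Expand (query, vertex) pairs to (query, incident face) pairs."""
        start = self._inc_ptr[vi]
        counts = self._inc_ptr[vi + 1] - start
        qi2 = np.repeat(qi, counts)
        total = int(counts.sum())
        base = np.repeat(np.cumsum(counts) - counts, counts)
        offsets = np.arange(total) - base
        fi2 = self._inc_faces[np.repeat(start, counts) + offsets]
        return qi2, fi2

    # -- closest point -----------------------------------------------------
    def closest_points(self, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Exact closest surface point for each query.

        Returns ``(points (k,3), squared_distances (k,), face_ids (k,))``.
        """
        q = np.atleast_2d(np.asarray(queries, dtype=float))

        # phase 1 — upper bound u: exact distance to the faces incident to the
        # nearest face-bearing vertex
        _, iv = self._vtree.query(q)
        nearest = self._used[iv]
        qi0, fi0 = self._expand_faces(np.arange(len(q)), nearest)
        pts0 = _closest_point_on_triangles(q[qi0], self.a[fi0], self.b[fi0], self.c[fi0])
        d20 = np.einsum("ij,ij->i", q[qi0] - pts0, q[qi0] - pts0)
        u = np.full(len(q), np.inf)
        np.minimum.at(u, qi0, d20)
        u = np.sqrt(u)

        # phase 2 — exact candidate set. A face beating the bound has some
        # vertex within u + (its max edge) of the query, so search each
        # edge-length class with its own radius.
        qi_parts, vi_parts = [], []
        for max_edge_c, members, tree in self._classes:
            lists = tree.query_ball_point(q, u + max_edge_c + 1e-9)
            qi_c = np.repeat(np.arange(len(q)), [len(lst) for lst in lists])
            vi_c = np.fromiter((v for lst in lists for v in lst), dtype=np.int64, count=len(qi_c))
            qi_parts.append(qi_c)
            vi_parts.append(members[vi_c])
        qi = np.concatenate(qi_parts)
        vi = np.concatenate(vi_parts)
        qi2, fi2 = self._expand_faces(qi, vi)
        # cheap lower bound |q - centroid| - R_face prunes faces that cannot
        # beat the phase-1 upper bound, then dedupe (query, face) pairs
        diff = q[qi2] - self._centroids[fi2]
        lb = np.sqrt(np.einsum("ij,ij->i", diff, diff)) - self._face_radius[fi2]
        keep = lb <= u[qi2] + 1e-12
        qi2, fi2 = qi2[keep], fi2[keep]
        key = qi2 * np.int64(len(self.a)) + fi2
        key, unique_idx = np.unique(key, return_index=True)
        qi2 = qi2[unique_idx]
        fi2 = fi2[unique_idx]
        pts = _closest_point_on_triangles(q[qi2], self.a[fi2], self.b[fi2], self.c[fi2])
        d2 = np.einsum("ij,ij->i", q[qi2] - pts, q[qi2] - pts)
        # per-query argmin with lowest-face-index tie break
        order = np.lexsort((fi2, d2, qi2))
        qi_sorted = qi2[order]
        first = np.searchsorted(qi_sorted, np.arange(len(q)))
        sel = order[first]
        return pts[sel], d2[sel], fi2[sel]

    # -- rays --------------------------------------------------------------
    def _ray_pairs(self, origins: np.ndarray, direction: np.ndarray):
        """Candidate (query, face) pairs whose projected triangle may cover the origin."""
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(d, ref)
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        basis = np.stack([u, v], axis=1)  # (3, 2)
        a2, b2, c2 = self.a @ basis, self.b @ basis, self.c @ basis
        cent2 = (a2 + b2 + c2) / 3.0
        rad = np.sqrt(
            np.maximum.reduce(
                [
                    np.einsum("ij,ij->i", a2 - cent2, a2 - cent2),
                    np.einsum("ij,ij->i", b2 - cent2, b2 - cent2),
                    np.einsum("ij,ij->i", c2 - cent2, c2 - cent2),
                ]
            )
        )
        o2 = origins @ basis
        # uniform-grid binning on projected centroids: any triangle covering a
        # query has its centroid within max circumradius, i.e. in the 3x3
        # neighborhood of the query's cell
        cell = float(rad.max()) + 1e-9
        lo = cent2.min(axis=0) - 2 * cell
        ckeys = np.floor((cent2 - lo) / cell).astype(np.int64)
        stride = np.int64(1) << 21  # far larger than any cell index span
        ckey = ckeys[:, 0] * stride + ckeys[:, 1]
        order = np.argsort(ckey, kind="stable")
        ckey_sorted = ckey[order]

        qcell = np.floor((o2 - lo) / cell).astype(np.int64)
        offs = np.array([[i, j] for i in (-1, 0, 1) for j in (-1, 0, 1)], dtype=np.int64)
        qkeys = ((qcell[:, None, 0] + offs[None, :, 0]) * stride
                 + (qcell[:, None, 1] + offs[None, :, 1])).ravel()
        left = np.searchsorted(ckey_sorted, qkeys, side="left")
        right = np.searchsorted(ckey_sorted, qkeys, side="right")
        counts = right - left
        total = int(counts.sum())
        qi = np.repeat(np.repeat(np.arange(len(origins)), 9), counts)
        base = np.repeat(np.cumsum(counts) - counts, counts)
        pos = np.repeat(left, counts) + (np.arange(total) - base)
        fi = order[pos]
        # prune by projected bounding box before the exact intersection test
        bb_lo = np.minimum(np.minimum(a2, b2), c2)
        bb_hi = np.maximum(np.maximum(a2, b2), c2)
        tol = 1e-9
        keep = (
            (o2[qi, 0] >= bb_lo[fi, 0] - tol) & (o2[qi, 0] <= bb_hi[fi, 0] + tol)
            & (o2[qi, 1] >= bb_lo[fi, 1] - tol) & (o2[qi, 1] <= bb_hi[fi, 1] + tol)
        )
        return qi[keep], fi[keep], d

    def _intersect_pairs(self, origins, qi, fi, d, interior_eps):
        """Möller–Trumbore as a line intersection (t of either sign).

        Direction-dependent per-face terms are computed once per unique face,
        then gathered per pair.
        """
        e1_all = self.b - self.a
        e2_all = self.c - self.a
        pvec_all = np.cross(np.broadcast_to(d, e2_all.shape), e2_all)
        det_all = np.einsum("ij,ij->i", e1_all, pvec_all)
        ok_all = np.abs(det_all) > _EPS
        inv_all = np.where(ok_all, 1.0 / np.where(det_all == 0, 1.0, det_all), 0.0)

        tvec = origins[qi] - self.a[fi]
        inv = inv_all[fi]
        u = np.einsum("ij,ij->i", tvec, pvec_all[fi]) * inv
        qvec = np.cross(tvec, e1_all[fi])
        vv = (qvec @ d) * inv
        t = np.einsum("ij,ij->i", e2_all[fi], qvec) * inv
        hit = ok_all[fi] & (u >= -interior_eps) & (vv >= -interior_eps) & (u + vv <= 1.0 + interior_eps)
        return hit, t

    def ray_nearest(self, origins: np.ndarray, direction: np.ndarray):
        """Smallest-|t| intersection with any triangle, searching both ways.

        Returns ``(t (k,), face_ids (k,), valid (k,))``; ``t`` is signed along
        ``direction``. Ties (same |t|) resolve to the lowest face index.
        """
        origins = np.atleast_2d(np.asarray(origins, dtype=float))
        qi, fi, d = self._ray_pairs(origins, direction)
        hit, t = self._intersect_pairs(origins, qi, fi, d, interior_eps=1e-9)
        qi, fi, t = qi[hit], fi[hit], t[hit]
        tvals = np.full(len(origins), np.nan)
        faces = np.full(len(origins), -1, dtype=np.int64)
        valid = np.zeros(len(origins), dtype=bool)
        if len(qi):
            order = np.lexsort((fi, np.abs(t), qi))
            qi_s = qi[order]
            first_idx = np.searchsorted(qi_s, np.arange(len(origins)))
            present = first_idx < len(qi_s)
            present[present] &= qi_s[first_idx[present]] == np.arange(len(origins))[present]
            sel = order[first_idx[present]]
            tvals[present] = t[sel]
            faces[present] = fi[sel]
            valid = present
        return tvals, faces, valid

    def ray_max(self, origins: np.ndarray, direction: np.ndarray):
        """Largest signed t intersection per ray (the surface point seen from
        far along ``direction`` — what a single-valued raster probe records).

        Returns ``(t (k,), valid (k,))``.
        """
        origins = np.atleast_2d(np.asarray(origins, dtype=float))
        qi, fi, d = self._ray_pairs(origins, direction)
        hit, t = self._intersect_pairs(origins, qi, fi, d, interior_eps=1e-9)
        qi, t = qi[hit], t[hit]
        tvals = np.full(len(origins), -np.inf)
        if len(qi):
            np.maximum.at(tvals, qi, t)
        valid = np.isfinite(tvals)
        tvals[~valid] = np.nan
        return tvals, valid

    def ray_hit_count(self, origins: np.ndarray, direction: np.ndarray, interior_only: bool = True) -> np.ndarray:
        """Number of triangle intersections per ray (both directions).

        With ``interior_only`` hits within 1e-7 of an edge are discarded, so
        a ray crossing a shared edge is not double counted.
        """
        origins = np.atleast_2d(np.asarray(origins, dtype=float))
        qi, fi, d = self._ray_pairs(origins, direction)
        eps = -1e-7 if interior_only else 1e-9
        hit, _ = self._intersect_pairs(origins, qi, fi, d, interior_eps=eps)
        return np.bincount(qi[hit], minlength=len(origins))


# -- single-query conveniences ----------------------------------------------

def closest_point(scan: SurfaceScan, query_point: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Exact closest point on the surface: ``(point, squared_distance, face_id)``."""
    soup = TriangleSoup(scan)
    pts, d2, fid = soup.closest_points(np.asarray(query_point, dtype=float)[None, :])
    return pts[0], float(d2[0]), int(fid[0])


def ray_intersect(scan: SurfaceScan, origin: np.ndarray, direction: np.ndarray):
    """Nearest intersection along a bidirectional ray.

    Returns ``(t, face_id)`` with ``t`` signed along ``direction``, or ``None``
    on a miss. ``direction`` must be unit length.
    """
    d = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    soup = TriangleSoup(scan)
    t, fid, valid = soup.ray_nearest(np.asarray(origin, dtype=float)[None, :], d)
    if not valid[0]:
        return None
    return float(t[0]), int(fid[0])


def ray_hit_count(scan: SurfaceScan, origin: np.ndarray, direction: np.ndarray) -> int:
    soup = TriangleSoup(scan)
    return int(soup.ray_hit_count(np.asarray(origin, dtype=float)[None, :], direction)[0])
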