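"""Types, geometry primitives and spatial queries of mesh_core."""
import numpy as np
import pytest

from wearbench.mesh_core import (
    Plane,
    RasterGrid,
    SurfaceScan,
    ValidationError,
    closest_point,
    fit_plane,
    grid_to_scan,
    ray_hit_count,
    ray_intersect,
    region_submesh,
    vertex_normals,
)
from wearbench.mesh_core.spatial import TriangleSoup

from oracles import brute_force_closest, brute_force_ray


def square_patch(z=0.0):
    """Two-triangle unit square at height z, labeled occlusal."""
    verts = np.array([[0, 0, z], [1, 0, z], [1, 1, z], [0, 1, z]], dtype=float)
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return SurfaceScan(verts, faces, ["occlusal"] * 4)


# --------------------------------------------------------------------------
# SurfaceScan / types
# --------------------------------------------------------------------------

class TestSurfaceScan:
    def test_basic_invariants(self):
        s = square_patch()
        assert s.n_vertices == 4 and s.n_faces == 2
        assert s.area() == pytest.approx(1.0)
        assert list(s.region_labels) == ["occlusal"] * 4

    def test_degenerate_faces_dropped(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float)
        faces = np.array([[0, 1, 2], [0, 1, 1], [0, 0, 0]])
        s = SurfaceScan(verts, faces)
        assert s.n_faces == 1

    def test_bad_inputs_raise(self):
        with pytest.raises(ValidationError):
            SurfaceScan(np.zeros((3, 3)), np.array([[0, 1, 5]]))
        with pytest.raises(ValidationError):
            SurfaceScan(np.array([[np.nan, 0, 0]]), np.zeros((0, 3), int))
        with pytest.raises(ValidationError):
            SurfaceScan(np.zeros((3, 3)), np.zeros((0, 3), int), ["occlusal"] * 2)
        with pytest.raises(ValidationError):
            SurfaceScan(np.zeros((1, 3)), np.zeros((0, 3), int), ["molar"])

    def test_crown_is_manifold_shell(self, small_crown):
        assert small_crown.is_manifold_with_boundary()

    def test_labels_default_other(self):
        s = SurfaceScan(np.eye(3), np.array([[0, 1, 2]]))
        assert list(s.region_labels) == ["other"] * 3


class TestRasterGrid:
    def test_invariants(self):
        with pytest.raises(ValidationError):
            RasterGrid(0.0, 50.0, np.zeros((3, 3)))
        g = RasterGrid(50.0, 50.0, np.zeros((3, 4)))
        assert g.shape == (3, 4)
        x, y = g.node_xy_mm()
        assert x[1] - x[0] == pytest.approx(0.05)

    def test_missing_cells(self):
        h = np.zeros((3, 3))
        h[1, 1] = np.nan
        g = RasterGrid(50, 50, h)
        assert g.valid_mask().sum() == 8


class TestPlane:
    def test_normalizes(self):
        p = Plane(np.array([0.0, 0.0, 2.0]), 3.0)
        assert np.allclose(p.normal, [0, 0, 1])
        assert p.offset == pytest.approx(1.5)
        assert p.signed_distance(np.array([0.0, 0.0, 2.0])) == pytest.approx(0.5)

    def test_project(self):
        p = Plane(np.array([0.0, 0.0, 1.0]), 1.0)
        q = p.project(np.array([[3.0, 4.0, 7.0]]))
        assert np.allclose(q, [[3, 4, 1]])


# --------------------------------------------------------------------------
# grid_to_scan
# --------------------------------------------------------------------------

class TestGridToScan:
    def test_flat_2x2(self):
        g = RasterGrid(50, 50, np.zeros((2, 2)))
        s = grid_to_scan(g)
        assert s.n_faces == 2
        assert s.area() == pytest.approx(0.05 * 0.05)

    def test_missing_center_skips_quads(self):
        h = np.zeros((3, 3))
        h[1, 1] = np.nan
        g = RasterGrid(50, 50, h)
        # oracle: enumerate quads with all 4 valid corners
        valid = np.isfinite(h)
        n_quads = sum(
            valid[i, j] and valid[i, j + 1] and valid[i + 1, j] and valid[i + 1, j + 1]
            for i in range(2)
            for j in range(2)
        )
        assert n_quads == 0
        with pytest.raises(ValidationError):
            grid_to_scan(g)

    def test_missing_corner(self):
        h = np.zeros((3, 3))
        h[0, 0] = np.nan
        g = RasterGrid(50, 50, h)
        s = grid_to_scan(g)
        valid = np.isfinite(h)
        n_quads = sum(
            valid[i, j] and valid[i, j + 1] and valid[i + 1, j] and valid[i + 1, j + 1]
            for i in range(2)
            for j in range(2)
        )
        assert s.n_faces == 2 * n_quads == 6

    def test_plane_z_equals_x_normals(self):
        xs = np.arange(4) * 0.05
        h = np.tile(xs, (4, 1))
        g = RasterGrid(50, 50, h)
        s = grid_to_scan(g)
        expect = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2)
        assert np.allclose(s.face_normals(), expect, atol=1e-12)

    def test_single_valued_no_undercuts(self, rng):
        h = rng.normal(0, 0.02, (8, 8))
        g = RasterGrid(100, 100, h)
        s = grid_to_scan(g)
        origins = np.column_stack(
            [rng.uniform(0.05, 0.65, 200), rng.uniform(0.05, 0.65, 200), np.full(200, -1.0)]
        )
        soup = TriangleSoup(s)
        counts = soup.ray_hit_count(origins, np.array([0.0, 0.0, 1.0]))
        assert counts.max() <= 1


# --------------------------------------------------------------------------
# vertex_normals
# --------------------------------------------------------------------------

class TestVertexNormals:
    def test_flat_patch(self):
        g = RasterGrid(50, 50, np.zeros((4, 4)))
        s = grid_to_scan(g)
        vn = vertex_normals(s)
        assert np.allclose(vn, [0, 0, 1])

    def test_sphere_against_analytic(self, rng):
        # triangulated unit sphere: normal at v should be v/|v|
        from scipy.spatial import ConvexHull

        # Fibonacci sphere: near-uniform triangulation of 10k points
        n = 10000
        i = np.arange(n)
        phi = np.pi * (3.0 - np.sqrt(5.0)) * i
        z = 1.0 - 2.0 * (i + 0.5) / n
        r = np.sqrt(1.0 - z * z)
        pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        hull = ConvexHull(pts)
        faces = hull.simplices.copy()
        # orient faces outward
        a, b, c = pts[faces[:, 0]], pts[faces[:, 1]], pts[faces[:, 2]]
        n = np.cross(b - a, c - a)
        flip = np.einsum("ij,ij->i", n, (a + b + c) / 3.0) < 0
        faces[flip] = faces[flip][:, [0, 2, 1]]
        s = SurfaceScan(pts, faces)
        vn = vertex_normals(s)
        cosang = np.clip(np.einsum("ij,ij->i", vn, pts), -1, 1)
        assert np.rad2deg(np.arccos(cosang)).max() < 2.0

    def test_winding_flip_negates(self, tiny_crown):
        flipped = SurfaceScan(
            tiny_crown.vertices.copy(),
            tiny_crown.faces[:, [0, 2, 1]].copy(),
            tiny_crown.region_labels.copy(),
        )
        assert np.allclose(vertex_normals(flipped), -vertex_normals(tiny_crown), atol=1e-12)

    def test_convex_shape_outward(self, rng):
        from scipy.spatial import ConvexHull

        pts = rng.normal(size=(500, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        hull = ConvexHull(pts)
        faces = hull.simplices.copy()
        a, b, c = pts[faces[:, 0]], pts[faces[:, 1]], pts[faces[:, 2]]
        n = np.cross(b - a, c - a)
        flip = np.einsum("ij,ij->i", n, (a + b + c) / 3.0) < 0
        faces[flip] = faces[flip][:, [0, 2, 1]]
        s = SurfaceScan(pts, faces)
        vn = vertex_normals(s)
        centroid = pts.mean(axis=0)
        assert np.all(np.einsum("ij,ij->i", vn, pts - centroid) > 0)


# --------------------------------------------------------------------------
# region_submesh
# --------------------------------------------------------------------------

class TestRegionSubmesh:
    def test_identity_when_all_labels(self, tiny_crown):
        sub, idx = region_submesh(tiny_crown, {"occlusal", "buccal", "lingual", "other"})
        assert sub.n_faces == tiny_crown.n_faces
        assert np.allclose(sub.vertices, tiny_crown.vertices[idx])

    def test_occlusal_excluded(self, tiny_crown):
        sub, idx = region_submesh(tiny_crown, {"buccal", "lingual"})
        assert "occlusal" not in set(sub.region_labels)
        assert len(np.unique(idx)) == len(idx)  # injective

    def test_partition_faces_disjoint(self, tiny_crown):
        occ, iocc = region_submesh(tiny_crown, {"occlusal"})
        rest, irest = region_submesh(tiny_crown, {"buccal", "lingual", "other"})
        occ_faces = {tuple(sorted(iocc[f])) for f in occ.faces}
        rest_faces = {tuple(sorted(irest[f])) for f in rest.faces}
        parent = {tuple(sorted(f)) for f in tiny_crown.faces}
        assert occ_faces.isdisjoint(rest_faces)
        assert occ_faces | rest_faces <= parent

    def test_partition_area_conserved(self, tiny_crown):
        # faces lost at label borders belong to no single-label cell; total of
        # per-label faces plus mixed faces must equal the parent exactly
        total = 0.0
        per_label_faces = 0
        for label in ("occlusal", "buccal", "lingual", "other"):
            try:
                sub, _ = region_submesh(tiny_crown, {label})
            except ValidationError:
                continue  # no pure face carries this label (e.g. a 1-row ring)
            total += sub.area()
            per_label_faces += sub.n_faces
        mixed = tiny_crown.n_faces - per_label_faces
        assert mixed >= 0
        labels = tiny_crown.region_labels[tiny_crown.faces]
        pure = (labels[:, 0] == labels[:, 1]) & (labels[:, 1] == labels[:, 2])
        pure_area = tiny_crown.face_areas()[pure].sum()
        assert total == pytest.approx(pure_area, rel=1e-9)

    def test_empty_result_raises(self):
        s = square_patch()
        with pytest.raises(ValidationError):
            region_submesh(s, {"lingual"})
        with pytest.raises(ValidationError):
            region_submesh(s, set())


# --------------------------------------------------------------------------
# fit_plane
# --------------------------------------------------------------------------

class TestFitPlane:
    def test_exact_horizontal(self, rng):
        pts = np.column_stack([rng.uniform(size=50), rng.uniform(size=50), np.full(50, 1.5)])
        p = fit_plane(pts, orient_along=[0, 0, 1])
        assert np.allclose(p.normal, [0, 0, 1], atol=1e-12)
        assert p.offset == pytest.approx(1.5)

    def test_diagonal_plane(self, rng):
        u = rng.uniform(-1, 1, 50)
        v = rng.uniform(-1, 1, 50)
        pts = np.column_stack([u, v, -u])  # x + z = 0
        p = fit_plane(pts)
        expect = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        assert np.allclose(np.abs(p.normal @ expect), 1.0, atol=1e-9)

    def test_noisy_plane_within_tolerance(self, rng):
        # oracle: the generating plane itself
        n_true = np.array([0.1, -0.2, 1.0])
        n_true /= np.linalg.norm(n_true)
        u, v = np.linalg.svd(np.eye(3) - np.outer(n_true, n_true))[0][:, :2].T
        coords = rng.uniform(-5, 5, (500, 2))
        pts = coords @ np.stack([u, v]) + rng.normal(0, 0.010, (500, 1)) * n_true
        p = fit_plane(pts, orient_along=n_true)
        ang = np.rad2deg(np.arccos(np.clip(p.normal @ n_true, -1, 1)))
        assert ang < 0.2

    def test_collinear_raises(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValidationError):
            fit_plane(pts)


# --------------------------------------------------------------------------
# closest_point / ray_intersect vs brute force
# --------------------------------------------------------------------------

class TestClosestPoint:
    def test_on_vertex(self):
        s = square_patch()
        pt, d2, fid = closest_point(s, s.vertices[2])
        assert d2 == pytest.approx(0.0, abs=1e-15)

    def test_above_patch(self):
        s = square_patch()
        pt, d2, fid = closest_point(s, [0.5, 0.5, 0.7])
        assert np.sqrt(d2) == pytest.approx(0.7)
        assert np.allclose(pt, [0.5, 0.5, 0.0])

    def test_against_brute_force(self, tiny_crown, rng):
        queries = rng.uniform([-5, -5, -2], [5, 5, 8], (100, 3))
        soup = TriangleSoup(tiny_crown)
        pts, d2, fid = soup.closest_points(queries)
        for i in range(len(queries)):
            _, d2_o, fid_o = brute_force_closest(tiny_crown, queries[i])
            assert d2[i] == pytest.approx(d2_o, abs=1e-12)
            assert fid[i] == fid_o or abs(d2[i] - d2_o) < 1e-12

    def test_empty_mesh_raises(self):
        s = SurfaceScan(np.eye(3), np.zeros((0, 3), int))
        with pytest.raises(ValidationError):
            closest_point(s, [0, 0, 0])


class TestRayIntersect:
    def test_hit_from_below(self):
        s = square_patch()
        t, fid = ray_intersect(s, [0.3, 0.3, -2.0], [0.0, 0.0, 1.0])
        assert t == pytest.approx(2.0)

    def test_parallel_misses(self):
        s = square_patch()
        assert ray_intersect(s, [0.3, 0.3, 1.0], [1.0, 0.0, 0.0]) is None

    def test_non_unit_direction_rejected(self):
        s = square_patch()
        with pytest.raises(ValueError):
            ray_intersect(s, [0, 0, 0], [0, 0, 2.0])

    def test_against_brute_force(self, tiny_crown, rng):
        soup = TriangleSoup(tiny_crown)
        for _ in range(100):
            origin = rng.uniform([-4, -4, -1], [4, 4, 6])
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            t, fid, valid = soup.ray_nearest(origin[None, :], d)
            hits = brute_force_ray(tiny_crown, origin, d)
            if not hits:
                assert not valid[0]
                continue
            assert valid[0]
            t_expected = min(hits, key=lambda h: (abs(h[0]), h[1]))
            assert t[0] == pytest.approx(t_expected[0], abs=1e-9)

    def test_undercut_multiplicity(self, small_crown):
        soup = TriangleSoup(small_crown)
        # below the buccal bulge a vertical line crosses the wall twice
        count = soup.ray_hit_count(np.array([[0.07, 3.62, 0.0]]), np.array([0.0, 0.0, 1.0]))
        assert count[0] >= 2
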