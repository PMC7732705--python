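"""Generators: crown, wear fields, capture models, pose, cohorts."""
import numpy as np
import pytest

from wearbench.mesh_core import ValidationError, region_submesh
from wearbench.mesh_core.spatial import TriangleSoup
from wearbench.synthetic_data import (
    CohortConfig,
    Lesion,
    LesionConfig,
    ScannerConfig,
    apply_reference_wear,
    apply_wear,
    generate_cohort,
    generate_crown,
    perturb_pose,
    simulate_intraoral,
    simulate_profilometer,
)

from conftest import SMALL_CROWN_KW

UP = np.array([0.0, 0.0, 1.0])


class TestGenerateCrown:
    def test_deterministic(self):
        a = generate_crown(11, **SMALL_CROWN_KW)
        b = generate_crown(11, **SMALL_CROWN_KW)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.faces, b.faces)
        assert np.array_equal(a.region_labels, b.region_labels)

    def test_different_seeds_differ(self):
        a = generate_crown(11, **SMALL_CROWN_KW)
        b = generate_crown(12, **SMALL_CROWN_KW)
        assert not np.array_equal(a.vertices, b.vertices)

    def test_occlusal_footprint_area(self, small_crown):
        occ, _ = region_submesh(small_crown, {"occlusal"})
        a, b, c = occ.triangle_corners()
        proj = 0.5 * np.abs(np.cross(b - a, c - a) @ UP)
        expect = np.pi * (0.35 * 10.0) ** 2
        assert abs(proj.sum() - expect) / expect < 0.15

    def test_has_undercut_on_bulge(self, small_crown):
        soup = TriangleSoup(small_crown)
        counts = soup.ray_hit_count(np.array([[0.07, 3.62, 0.0]]), UP)
        assert counts[0] >= 2

    def test_regions_present_and_manifold(self, small_crown):
        assert set(small_crown.region_labels) == {"occlusal", "buccal", "lingual", "other"}
        assert small_crown.is_manifold_with_boundary()


class TestLesions:
    def test_gaussian_closed_form(self):
        les = Lesion(shape="gaussian", amplitude_mm=0.5, sigma_mm=1.0)
        assert les.analytic_volume_mm3 == pytest.approx(2 * np.pi * 0.5 * 1.0**2)

    def test_cap_closed_form(self):
        les = Lesion(shape="spherical_cap", amplitude_mm=0.3, cap_radius_mm=1.2)
        h, r = 0.3, 1.2
        assert les.analytic_volume_mm3 == pytest.approx(np.pi * h * h * (3 * r - h) / 3)

    def test_quadrature_matches_closed_form(self):
        # 10 um evaluation grid over the lesion support
        les = Lesion(shape="gaussian", amplitude_mm=0.5, sigma_mm=0.6)
        step = 0.01
        g = np.arange(-3.0, 3.0 + step, step)
        u, v = np.meshgrid(g, g)
        total = les.depth(u.ravel(), v.ravel()).sum() * step * step
        assert abs(total - les.analytic_volume_mm3) / les.analytic_volume_mm3 < 0.005

    def test_invalid_parameters(self):
        with pytest.raises(ValidationError):
            Lesion(amplitude_mm=-0.1)
        with pytest.raises(ValidationError):
            Lesion(shape="spherical_cap", amplitude_mm=2.0, cap_radius_mm=1.0)
        with pytest.raises(ValidationError):
            Lesion(shape="cone")


class TestApplyWear:
    def test_empty_lesions_identity(self, small_crown):
        worn, vol = apply_wear(small_crown, LesionConfig(()))
        assert vol == 0.0
        assert np.array_equal(worn.vertices, small_crown.vertices)

    def test_non_occlusal_conserved_bitwise(self, small_crown):
        worn, _ = apply_wear(
            small_crown, LesionConfig((Lesion(amplitude_mm=0.4, sigma_mm=0.8),))
        )
        m = ~small_crown.region_mask("occlusal")
        assert np.array_equal(worn.vertices[m], small_crown.vertices[m])

    def test_true_volume_closed_form(self, small_crown):
        cfg = LesionConfig((Lesion(amplitude_mm=0.5, sigma_mm=1.0),))
        _, vol = apply_wear(small_crown, cfg)
        assert vol == pytest.approx(2 * np.pi * 0.5, rel=1e-12)

    def test_lesion_outside_footprint_raises(self, small_crown):
        cfg = LesionConfig((Lesion(center=(9.0, 0.0), amplitude_mm=0.2, sigma_mm=0.5),))
        with pytest.raises(ValidationError):
            apply_wear(small_crown, cfg)

    def test_too_deep_raises(self, small_crown):
        cfg = LesionConfig((Lesion(amplitude_mm=6.0, sigma_mm=1.0),))
        with pytest.raises(ValidationError):
            apply_wear(small_crown, cfg)


class TestReferenceWear:
    def test_zero_depth_identity(self, small_crown):
        out = apply_reference_wear(small_crown, 0.0)
        assert np.array_equal(out.vertices, small_crown.vertices)

    def test_erodes_inward_only_in_region(self, small_crown):
        out = apply_reference_wear(small_crown, 60.0, regions=("buccal",), patch_center_deg=90.0)
        disp = out.vertices - small_crown.vertices
        moved = np.linalg.norm(disp, axis=1) > 1e-9
        assert set(small_crown.region_labels[moved]) == {"buccal"}
        # inward at the +y wall means negative mean y displacement
        assert disp[moved, 1].mean() < 0
        assert np.linalg.norm(disp, axis=1).max() <= 60e-3 + 1e-9


class TestProfilometer:
    def test_flat_plane_noise_free_exact(self):
        from wearbench.mesh_core import RasterGrid, SurfaceScan, grid_to_scan

        g = RasterGrid(100, 100, np.full((30, 30), 2.0))
        plane = grid_to_scan(g)
        cap = simulate_profilometer(plane, ScannerConfig(step_um=100, noise_sd_um=0.0))
        assert np.allclose(cap.vertices[:, 2], 2.0, atol=1e-9)

    def test_removes_undercuts(self, small_crown):
        cap = simulate_profilometer(small_crown, ScannerConfig(step_um=100, seed=2))
        soup = TriangleSoup(cap)
        rng = np.random.default_rng(0)
        o = np.column_stack(
            [rng.uniform(-4, 4, 300), rng.uniform(-4, 4, 300), np.zeros(300)]
        )
        assert soup.ray_hit_count(o, UP).max() <= 1

    def test_noise_sd_recovered(self):
        # oracle: z-residuals at grid nodes of a flat plane recover the 2.6 um sd
        from wearbench.mesh_core import RasterGrid, grid_to_scan

        g = RasterGrid(100, 100, np.zeros((110, 110)))
        plane = grid_to_scan(g)
        cap = simulate_profilometer(plane, ScannerConfig(step_um=100, noise_sd_um=2.6, seed=9))
        resid_um = cap.vertices[:, 2] * 1e3
        assert len(resid_um) >= 10000
        assert abs(np.std(resid_um) - 2.6) / 2.6 < 0.10

    def test_wrong_capture_model_rejected(self, small_crown):
        with pytest.raises(ValidationError):
            simulate_profilometer(small_crown, ScannerConfig(capture_model="intraoral"))


class TestIntraoral:
    def test_disabled_everything_is_identity(self, small_crown):
        cfg = ScannerConfig(
            capture_model="intraoral", noise_sd_um=0.0,
            smoothing_iterations=0, remesh_edge_mm=None,
        )
        cap = simulate_intraoral(small_crown, cfg)
        assert np.array_equal(cap.vertices, small_crown.vertices)
        assert np.array_equal(cap.faces, small_crown.faces)

    def test_smoothing_lowers_sharp_peak(self):
        # a sharp gaussian bump loses height under Laplacian smoothing
        from wearbench.mesh_core import RasterGrid, grid_to_scan

        g = np.arange(-1.0, 1.01, 0.05)
        u, v = np.meshgrid(g, g)
        h = 0.8 * np.exp(-(u**2 + v**2) / (2 * 0.15**2))
        plane = grid_to_scan(RasterGrid(50, 50, h))
        cfg = ScannerConfig(
            capture_model="intraoral", noise_sd_um=0.0,
            smoothing_iterations=5, smoothing_lambda=0.5, remesh_edge_mm=None,
        )
        cap = simulate_intraoral(plane, cfg)
        assert cap.vertices[:, 2].max() < plane.vertices[:, 2].max()

    def test_undercut_survives(self, small_crown):
        cap = simulate_intraoral(
            small_crown, ScannerConfig(capture_model="intraoral", noise_sd_um=2.0, seed=4)
        )
        soup = TriangleSoup(cap)
        # probe a fan of vertical lines through the (smoothed) buccal bulge
        ys = np.arange(3.5, 3.9, 0.02)
        origins = np.column_stack([np.full_like(ys, 0.07), ys, np.full_like(ys, 0.5)])
        assert soup.ray_hit_count(origins, UP).max() >= 2

    def test_remesh_coarsens(self, small_crown):
        cap = simulate_intraoral(
            small_crown,
            ScannerConfig(capture_model="intraoral", remesh_edge_mm=0.4, seed=4),
        )
        assert cap.n_vertices < small_crown.n_vertices / 2


class TestPerturbPose:
    def test_zero_bounds_identity(self, tiny_crown):
        moved, t = perturb_pose(tiny_crown, 0.0, 0.0, seed=3)
        assert t.almost_equal(__import__("wearbench").RigidTransform.identity())
        assert np.allclose(moved.vertices, tiny_crown.vertices)

    def test_inverse_restores(self, tiny_crown):
        moved, t = perturb_pose(tiny_crown, 5.0, 2.0, seed=3)
        back = moved.transformed(t.inverse())
        assert np.allclose(back.vertices, tiny_crown.vertices, atol=1e-12)

    def test_deterministic(self, tiny_crown):
        _, t1 = perturb_pose(tiny_crown, 5.0, 2.0, seed=3)
        _, t2 = perturb_pose(tiny_crown, 5.0, 2.0, seed=3)
        assert t1.almost_equal(t2, atol=0)

    def test_bounds_respected(self, tiny_crown):
        for seed in range(5):
            _, t = perturb_pose(tiny_crown, 5.0, 2.0, seed=seed)
            assert t.rotation_angle_deg() <= 5.0 + 1e-9
            assert np.all(np.abs(t.translation) <= 2.0 + 1e-12)


class TestCohort:
    @pytest.fixture(scope="class")
    def cohort(self):
        from conftest import scaled_cohort_config

        return generate_cohort(scaled_cohort_config(3, seed=7))

    def test_bundle_shape(self, cohort):
        bundles, truth = cohort
        assert len(bundles) == 3 and len(truth) == 3
        for b in bundles:
            assert len(b.scans) == 4  # 2 models x 2 timepoints
            for model in ("profilometer", "intraoral"):
                for tp in ("baseline", "followup"):
                    assert (model, tp) in b.scans

    def test_deterministic(self):
        from conftest import scaled_cohort_config

        _, t1 = generate_cohort(scaled_cohort_config(2, seed=9))
        _, t2 = generate_cohort(scaled_cohort_config(2, seed=9))
        assert t1.equals(t2)

    def test_truth_attached_to_ideal_surface(self, cohort):
        bundles, truth = cohort
        for b, (_, row) in zip(bundles, truth.iterrows()):
            assert b.true_volume_mm3 == pytest.approx(row.true_volume_mm3)
            assert b.true_volume_mm3 == pytest.approx(b.lesions.true_volume_mm3)

    def test_followups_share_one_pose(self, cohort):
        bundles, _ = cohort
        for b in bundles:
            # undoing the recorded transform puts both follow-ups back into
            # the canonical (near-baseline) pose
            inv = b.true_transform.inverse()
            for model in ("profilometer", "intraoral"):
                f = b.scans[(model, "followup")].transformed(inv)
                base = b.scans[(model, "baseline")]
                # centroids agree to within wear + capture differences
                assert np.linalg.norm(
                    f.vertices.mean(axis=0) - base.vertices.mean(axis=0)
                ) < 0.25

    def test_lognormal_amplitude_moments(self):
        # Monte-Carlo mean of true volumes vs analytic moment of the
        # generating distribution (3 sd band), n = 200 draws
        from wearbench.synthetic_data import draw_lesions
        from conftest import scaled_cohort_config

        cfg = scaled_cohort_config(1, seed=0, lesion_count_range=(1, 1))
        rng = np.random.default_rng(42)
        vols = np.array(
            [draw_lesions(rng, cfg).true_volume_mm3 for _ in range(200)]
        )
        # analytic: E[V] = 2*pi*E[a]*E[sigma^2] (a and sigma independent)
        med, slog = cfg.lesion_amp_median_mm, cfg.lesion_amp_sigma_log
        e_amp = med * np.exp(slog**2 / 2)  # clipping ignored: negligible mass
        lo, hi = cfg.lesion_sigma_range_mm
        e_sig2 = (hi**3 - lo**3) / (3 * (hi - lo))
        expect = 2 * np.pi * e_amp * e_sig2
        se = vols.std(ddof=1) / np.sqrt(len(vols))
        assert abs(vols.mean() - expect) < 3 * se
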