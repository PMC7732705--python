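"""Rigid alignment of follow-up to baseline scans.

Two strategies are provided, mirroring the two analysis styles under
comparison:

``align_bestfit_style``
    the occlusal region is deleted from both scans, then untrimmed
    point-to-plane ICP runs in two stages (1000 then 5000 sampled points),
    initialized from principal axes + centroid. No correspondence
    rejection — every sampled point votes, worn or not.

``align_feature_trimmed_style``
    a feature-based coarse alignment (curvature keypoints + rotation-
    invariant descriptors + RANSAC) on the full scans, then distance-trimmed
    ICP restricted to the buccal/lingual reference submeshes with a 25 µm
    inlier band (annealed from the current residual down to the band, so the
    trim is re-evaluated every iteration).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .mesh_core import SurfaceScan, ValidationError, region_submesh, vertex_normals
from .mesh_core.spatial import TriangleSoup
from .transforms import RigidTransform, orthonormalize

__all__ = [
    "AlignmentConfig",
    "AlignmentReport",
    "DegenerateAlignmentError",
    "sample_surface_points",
    "icp",
    "feature_global_align",
    "align_bestfit_style",
    "align_feature_trimmed_style",
]

REFERENCE_REGIONS = ("buccal", "lingual")


class DegenerateAlignmentError(RuntimeError):
    """Raised when too few correspondences remain to solve for a pose."""


@dataclass(frozen=True)
class AlignmentConfig:
    """Parameters of one alignment run.

    ``coarse_sample_n``/``fine_sample_n`` default to the 1000/5000 two-stage
    sampling; ``inlier_threshold_um`` (feature_trimmed only) defaults to the
    25 µm correspondence band.
    """

    strategy: str = "bestfit"  # bestfit | feature_trimmed
    coarse_sample_n: int = 1000
    fine_sample_n: int = 5000
    inlier_threshold_um: float = 25.0
    max_iterations: int = 100
    convergence_tol_um: float = 0.1
    metric: str = "point_to_plane"  # point_to_plane | point_to_point
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in {"bestfit", "feature_trimmed"}:
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        if self.coarse_sample_n <= 0 or self.fine_sample_n <= 0:
            raise ValidationError("sample sizes must be positive")
        if self.inlier_threshold_um <= 0:
            raise ValidationError("inlier threshold must be positive")
        if self.metric not in {"point_to_plane", "point_to_point"}:
            raise ValidationError(f"unknown metric {self.metric!r}")


@dataclass
class AlignmentReport:
    transform: RigidTransform
    iterations: int
    rms_um: float
    inlier_fraction: float
    residual_trace_um: list[float] = field(default_factory=list)
    strategy: str = ""
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.rms_um < 0:
            raise ValidationError("RMS residual must be >= 0")
        if not (0.0 < self.inlier_fraction <= 1.0):
            raise ValidationError("inlier fraction must be in (0, 1]")


# --------------------------------------------------------------------------
# Sampling
# --------------------------------------------------------------------------

def sample_surface_points(scan: SurfaceScan, n: int, seed: int):
    """Area-uniform random points on the triangle set.

    Returns ``(points (n,3), normals (n,3))`` with normals taken from the
    source faces. Deterministic given ``seed``.
    """
    if n < 3:
        raise ValidationError("need at least 3 sample points")
    if scan.n_faces == 0:
        raise ValidationError("cannot sample an empty mesh")
    rng = np.random.default_rng(seed)
    areas = scan.face_areas()
    probs = areas / areas.sum()
    fid = rng.choice(scan.n_faces, size=n, p=probs)
    # uniform barycentric via the square-root trick
    r1 = np.sqrt(rng.uniform(size=n))
    r2 = rng.uniform(size=n)
    a, b, c = scan.triangle_corners()
    pts = (
        (1.0 - r1)[:, None] * a[fid]
        + (r1 * (1.0 - r2))[:, None] * b[fid]
        + (r1 * r2)[:, None] * c[fid]
    )
    return pts, scan.face_normals()[fid]


# --------------------------------------------------------------------------
# Rigid solvers
# --------------------------------------------------------------------------

def _solve_point_to_point(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Closed-form SVD (Kabsch) solve; reflections corrected by sign flip."""
    sc = src.mean(axis=0)
    dc = dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform.from_rotation_translation(r, dc - r @ sc)


def _solve_point_to_plane(src: np.ndarray, dst: np.ndarray, normals: np.ndarray) -> RigidTransform:
    """Linearized least-squares point-to-plane solve, re-orthonormalized."""
    b = np.einsum("ij,ij->i", dst - src, normals)
    a = np.concatenate([np.cross(src, normals), normals], axis=1)
    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    rx, ry, rz = x[:3]
    r_lin = np.array([[1.0, -rz, ry], [rz, 1.0, -rx], [-ry, rx, 1.0]])
    r = orthonormalize(r_lin)
    return RigidTransform.from_rotation_translation(r, x[3:])


# --------------------------------------------------------------------------
# ICP
# --------------------------------------------------------------------------

def icp(
    fixed: SurfaceScan,
    moving_points: np.ndarray,
    cfg: AlignmentConfig,
    initial: RigidTransform | None = None,
    trimmed: bool = False,
    fixed_soup: TriangleSoup | None = None,
) -> AlignmentReport:
    """Iterative closest point from sampled moving points onto a fixed surface.

    Each iteration: exact closest-point correspondences, optional distance
    trimming (the inlier band anneals from a robust median-based scale of the
    current residuals down to ``inlier_threshold_um``, re-evaluated every
    pass), rigid solve
    (point-to-point Kabsch or linearized point-to-plane), apply. Terminates
    when the inlier RMS improves by less than ``convergence_tol_um`` or at
    ``max_iterations``.
    """
    pts = np.asarray(moving_points, dtype=float)
    if len(pts) < 3:
        raise DegenerateAlignmentError("need at least 3 moving points")
    soup = fixed_soup if fixed_soup is not None else TriangleSoup(fixed)
    transform = initial if initial is not None else RigidTransform.identity()
    thr_mm = cfg.inlier_threshold_um * 1e-3
    trace: list[float] = []
    prev_rms = np.inf
    inlier_fraction = 1.0
    rms_um = 0.0
    iterations = 0

    for iterations in range(1, cfg.max_iterations + 1):
        moved = transform.apply(pts)
        cp, d2, fid = soup.closest_points(moved)
        dist = np.sqrt(d2)
        if trimmed:
            # anneal the band from a robust scale of the current residuals
            # (median is immune to a minority of gross outliers) down to the
            # configured inlier threshold, re-evaluated every iteration
            robust = 3.0 * 1.4826 * float(np.median(dist))
            band = max(thr_mm, robust) if np.isfinite(prev_rms) else np.inf
            mask = dist <= band
        else:
            mask = np.ones(len(dist), dtype=bool)
        if mask.sum() < 3:
            raise DegenerateAlignmentError(
                f"only {int(mask.sum())} correspondences within the inlier band"
            )
        rms = float(np.sqrt(np.mean(dist[mask] ** 2)))
        rms_um = rms * 1e3
        inlier_fraction = float(mask.mean())
        trace.append(rms_um)
        if abs(prev_rms - rms) * 1e3 < cfg.convergence_tol_um:
            break
        prev_rms = rms
        src = moved[mask]
        dst = cp[mask]
        if cfg.metric == "point_to_point":
            step = _solve_point_to_point(src, dst)
        else:
            step = _solve_point_to_plane(src, dst, soup.face_normals[fid[mask]])
        transform = step @ transform

    return AlignmentReport(
        transform=transform,
        iterations=iterations,
        rms_um=rms_um,
        inlier_fraction=inlier_fraction,
        residual_trace_um=trace,
    )


# --------------------------------------------------------------------------
# Coarse initializers
# --------------------------------------------------------------------------

def principal_axes_align(
    fixed: SurfaceScan,
    moving: SurfaceScan,
    seed: int = 0,
    n_check: int = 300,
    fixed_soup: TriangleSoup | None = None,
) -> RigidTransform:
    """Centroid + covariance-eigenvector alignment.

    Eigenvector sign ambiguity (4 proper-rotation combinations) is resolved
    by picking the candidate with the lowest sampled closest-point RMS.
    """
    soup = fixed_soup if fixed_soup is not None else TriangleSoup(fixed)
    probe, _ = sample_surface_points(moving, n_check, seed)

    def axes(scan):
        v = scan.vertices
        c = v.mean(axis=0)
        _, vec = np.linalg.eigh(np.cov((v - c).T))
        vec = vec[:, ::-1]  # descending eigenvalue order
        if np.linalg.det(vec) < 0:
            vec = vec.copy()
            vec[:, 2] *= -1
        return c, vec

    cf, vf = axes(fixed)
    cm, vm = axes(moving)
    best = None
    best_rms = np.inf
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        s = np.diag([sx, sy, sx * sy])  # keeps det = +1
        r = vf @ s @ vm.T
        cand = RigidTransform.from_rotation_translation(r, cf - r @ cm)
        _, d2, _ = soup.closest_points(cand.apply(probe))
        rms = float(np.sqrt(d2.mean()))
        if rms < best_rms:
            best_rms = rms
            best = cand
    return best


def _keypoints_and_descriptors(
    scan: SurfaceScan,
    max_keypoints: int = 120,
    nms_radius_mm: float = 0.5,
    scales_mm: tuple[float, ...] = (0.4, 0.8, 1.2),
    n_bins: int = 6,
):
    """Curvature keypoints with multi-scale normal-deviation histograms.

    Descriptors are histograms of cos(angle) between the keypoint normal and
    neighbor normals inside balls of several radii — rotation invariant by
    construction.
    """
    vn = vertex_normals(scan)
    tree = cKDTree(scan.vertices)
    # curvature proxy: mean angular deviation of normals in the smallest scale
    pairs = tree.query_pairs(scales_mm[0] / 2.0, output_type="ndarray")
    curv = np.zeros(scan.n_vertices)
    cnt = np.zeros(scan.n_vertices)
    dots = np.einsum("ij,ij->i", vn[pairs[:, 0]], vn[pairs[:, 1]])
    dev = 1.0 - np.clip(dots, -1.0, 1.0)
    np.add.at(curv, pairs[:, 0], dev)
    np.add.at(curv, pairs[:, 1], dev)
    np.add.at(cnt, pairs[:, 0], 1.0)
    np.add.at(cnt, pairs[:, 1], 1.0)
    curv = np.where(cnt > 0, curv / np.maximum(cnt, 1.0), 0.0)

    order = np.argsort(-curv, kind="stable")
    kept: list[int] = []
    kept_pts = []
    for idx in order:
        if len(kept) >= max_keypoints:
            break
        p = scan.vertices[idx]
        if kept_pts and np.min(np.linalg.norm(np.array(kept_pts) - p, axis=1)) < nms_radius_mm:
            continue
        kept.append(int(idx))
        kept_pts.append(p)
    kept = np.array(kept, dtype=np.int64)
    if len(kept) == 0:
        return kept, np.zeros((0, len(scales_mm) * n_bins)), vn

    # per scale: histogram of normal deviation plus histogram of neighbor
    # heights above the keypoint's tangent plane (bump/saddle/flat signature);
    # both are invariant under rigid motion
    bins = np.linspace(-1.0, 1.0, n_bins + 1)
    hbins = np.linspace(-0.45, 0.45, n_bins + 1)
    desc = np.zeros((len(kept), 2 * len(scales_mm) * n_bins + 2))
    for si, radius in enumerate(scales_mm):
        lists = tree.query_ball_point(scan.vertices[kept], radius)
        for ki, nbrs in enumerate(lists):
            d = np.clip(vn[nbrs] @ vn[kept[ki]], -1.0, 1.0)
            h, _ = np.histogram(d, bins=bins)
            total = h.sum()
            off = 2 * si * n_bins
            if total > 0:
                desc[ki, off: off + n_bins] = h / total
            rel = scan.vertices[nbrs] - scan.vertices[kept[ki]]
            heights = np.clip((rel @ vn[kept[ki]]) / radius, -0.449, 0.449)
            h2, _ = np.histogram(heights, bins=hbins)
            if h2.sum() > 0:
                desc[ki, off + n_bins: off + 2 * n_bins] = h2 / h2.sum()
    # two extra rigid-invariant channels: scaled radial distance from the
    # scan centroid, and local curvature — cheap disambiguation between
    # near-identical bumps
    centroid = scan.vertices.mean(axis=0)
    radial = np.linalg.norm(scan.vertices[kept] - centroid, axis=1)
    desc[:, -2] = radial / max(radial.max(), 1e-9)
    cmax = max(curv[kept].max(), 1e-12)
    desc[:, -1] = curv[kept] / cmax
    return kept, desc, vn, curv


def feature_global_align(
    fixed: SurfaceScan,
    moving: SurfaceScan,
    seed: int = 0,
    ransac_iterations: int = 1200,
    consensus_radius_mm: float = 0.6,
    min_consensus: int = 10,
) -> RigidTransform:
    """Coarse rigid alignment from descriptor matches + RANSAC.

    Falls back to principal-axes + centroid alignment (with a warning) when
    consensus stays below ``min_consensus`` matches — e.g. on featureless
    surfaces with no stable keypoints.
    """
    rng = np.random.default_rng(seed)
    kf, df, _, curv_f = _keypoints_and_descriptors(fixed)
    km, dm, _, _ = _keypoints_and_descriptors(moving)
    # keypoints must be genuine curvature peaks: on a featureless surface
    # (e.g. a sphere) keypoint curvature matches the surface-wide median and
    # matching would be arbitrary, so take the fallback path instead
    contrast = float(
        np.median(curv_f[kf]) / (np.median(curv_f) + 1e-12)
    ) if len(kf) else 0.0
    if contrast > 2.0 and len(kf) >= 3 and len(km) >= 3:
        pf = fixed.vertices[kf]
        pm = moving.vertices[km]
        # mutual nearest-descriptor matches
        dist = np.linalg.norm(dm[:, None, :] - df[None, :, :], axis=2)
        m2f = np.argmin(dist, axis=1)
        f2m = np.argmin(dist, axis=0)
        mutual = f2m[m2f] == np.arange(len(km))
        if mutual.sum() >= 3:
            src = pm[mutual]
            dst = pf[m2f[mutual]]
        else:
            src = pm
            dst = pf[m2f]

        best_transform = None
        best_count = 0
        n = len(src)
        for _ in range(ransac_iterations):
            pick = rng.choice(n, 3, replace=False)
            s3, d3 = src[pick], dst[pick]
            # rigidity prefilter: pairwise distances must be compatible
            ds = np.linalg.norm(s3 - np.roll(s3, 1, axis=0), axis=1)
            dd = np.linalg.norm(d3 - np.roll(d3, 1, axis=0), axis=1)
            if np.any(np.abs(ds - dd) > consensus_radius_mm) or np.min(ds) < 1e-6:
                continue
            cand = _solve_point_to_point(s3, d3)
            err = np.linalg.norm(cand.apply(src) - dst, axis=1)
            count = int((err < consensus_radius_mm).sum())
            if count > best_count:
                best_count = count
                best_transform = _solve_point_to_point(
                    src[err < consensus_radius_mm], dst[err < consensus_radius_mm]
                )
        if best_transform is not None and best_count >= min_consensus:
            return best_transform

    warnings.warn(
        "feature consensus too low; falling back to principal-axes alignment",
        RuntimeWarning,
        stacklevel=2,
    )
    return principal_axes_align(fixed, moving, seed=seed)


# --------------------------------------------------------------------------
# Full strategies
# --------------------------------------------------------------------------

def _reference_submesh(scan: SurfaceScan) -> SurfaceScan:
    sub, _ = region_submesh(scan, set(REFERENCE_REGIONS))
    return sub


def align_bestfit_style(
    baseline: SurfaceScan, followup: SurfaceScan, cfg: AlignmentConfig | None = None
) -> tuple[AlignmentReport, SurfaceScan]:
    """Untrimmed two-stage best-fit ICP on the reference surfaces.

    The occlusal region is removed from both scans; ICP runs with
    ``coarse_sample_n`` then ``fine_sample_n`` points from the follow-up
    reference surfaces, initialized from principal axes + centroid; the
    composed transform is applied to the complete follow-up scan.
    """
    cfg = cfg or AlignmentConfig(strategy="bestfit")
    fixed_ref = _reference_submesh(baseline)
    moving_ref = _reference_submesh(followup)
    soup = TriangleSoup(fixed_ref)

    init = principal_axes_align(fixed_ref, moving_ref, seed=cfg.seed, fixed_soup=soup)
    pts_coarse, _ = sample_surface_points(moving_ref, cfg.coarse_sample_n, cfg.seed)
    rep1 = icp(fixed_ref, pts_coarse, cfg, initial=init, trimmed=False, fixed_soup=soup)
    pts_fine, _ = sample_surface_points(moving_ref, cfg.fine_sample_n, cfg.seed + 1)
    rep2 = icp(fixed_ref, pts_fine, cfg, initial=rep1.transform, trimmed=False, fixed_soup=soup)

    report = AlignmentReport(
        transform=rep2.transform,
        iterations=rep1.iterations + rep2.iterations,
        rms_um=rep2.rms_um,
        inlier_fraction=rep2.inlier_fraction,
        residual_trace_um=rep1.residual_trace_um + rep2.residual_trace_um,
        strategy="bestfit",
    )
    return report, followup.transformed(rep2.transform)


def align_feature_trimmed_style(
    baseline: SurfaceScan, followup: SurfaceScan, cfg: AlignmentConfig | None = None
) -> tuple[AlignmentReport, SurfaceScan]:
    """Feature-initialized, distance-trimmed ICP on the reference surfaces.

    Coarse: feature-based global alignment on the full scans. Fine: trimmed
    ICP restricted to the buccal/lingual submeshes with the 25 µm inlier
    band; raises :class:`DegenerateAlignmentError` rather than silently
    proceeding when almost nothing falls inside the band.
    """
    cfg = cfg or AlignmentConfig(strategy="feature_trimmed")
    coarse = feature_global_align(baseline, followup, seed=cfg.seed)

    fixed_ref = _reference_submesh(baseline)
    moving_ref = _reference_submesh(followup)
    soup = TriangleSoup(fixed_ref)
    pts, _ = sample_surface_points(moving_ref, cfg.fine_sample_n, cfg.seed)
    rep = icp(fixed_ref, pts, cfg, initial=coarse, trimmed=True, fixed_soup=soup)

    report = AlignmentReport(
        transform=rep.transform,
        iterations=rep.iterations,
        rms_um=rep.rms_um,
        inlier_fraction=rep.inlier_fraction,
        residual_trace_um=rep.residual_trace_um,
        strategy="feature_trimmed",
    )
    return report, followup.transformed(rep.transform)
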