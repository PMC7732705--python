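"""Synthetic dental-scan generator with exact ground truth.

Produces baseline/follow-up scan pairs of a crown-like surface under three
capture models:

``ideal``
    the generator mesh itself;
``profilometer``
    single-valued raster resampling on a 50 µm step grid with 2.6 µm
    repeatability noise — undercuts are invisible by construction;
``intraoral``
    coarser remeshing (vertex clustering), Laplacian smoothing and vertex
    noise — undercuts are retained, fine topography is attenuated.

Wear is applied as a depth field along the occlusal-plane normal, so the
removed volume has a closed form and serves as an uncontestable oracle for
the measurement pipeline.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mesh_core import (
    RasterGrid,
    SurfaceScan,
    ValidationError,
    fit_plane,
    grid_to_scan,
    region_submesh,
    vertex_normals,
)
from .mesh_core.spatial import TriangleSoup
from .transforms import RigidTransform

__all__ = [
    "Lesion",
    "LesionConfig",
    "ScannerConfig",
    "CohortConfig",
    "ScanPairBundle",
    "generate_crown",
    "apply_wear",
    "apply_reference_wear",
    "simulate_profilometer",
    "simulate_intraoral",
    "simulate_capture",
    "perturb_pose",
    "generate_cohort",
]


# --------------------------------------------------------------------------
# Configs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Lesion:
    """One wear lesion expressed in occlusal-plane coordinates (mm)."""

    shape: str = "gaussian"  # gaussian | spherical_cap
    center: tuple[float, float] = (0.0, 0.0)
    amplitude_mm: float = 0.3  # gaussian peak depth, or cap height h
    sigma_mm: float = 0.7  # gaussian sigma
    cap_radius_mm: float = 1.0  # sphere radius r (spherical_cap only)

    def __post_init__(self):
        if self.shape not in {"gaussian", "spherical_cap"}:
            raise ValidationError(f"unknown lesion shape {self.shape!r}")
        if self.amplitude_mm <= 0 or self.sigma_mm <= 0 or self.cap_radius_mm <= 0:
            raise ValidationError("lesion parameters must be positive")
        if self.shape == "spherical_cap" and self.amplitude_mm > self.cap_radius_mm:
            raise ValidationError("cap height cannot exceed the sphere radius")

    def depth(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Depth field (mm, >= 0) at in-plane coordinates (u, v)."""
        du = u - self.center[0]
        dv = v - self.center[1]
        d2 = du * du + dv * dv
        if self.shape == "gaussian":
            return self.amplitude_mm * np.exp(-d2 / (2.0 * self.sigma_mm**2))
        r, h = self.cap_radius_mm, self.amplitude_mm
        inside = np.sqrt(np.maximum(r * r - d2, 0.0)) - (r - h)
        return np.maximum(inside, 0.0)

    @property
    def analytic_volume_mm3(self) -> float:
        if self.shape == "gaussian":
            return float(2.0 * np.pi * self.amplitude_mm * self.sigma_mm**2)
        r, h = self.cap_radius_mm, self.amplitude_mm
        return float(np.pi * h * h * (3.0 * r - h) / 3.0)


@dataclass(frozen=True)
class LesionConfig:
    lesions: tuple[Lesion, ...] = ()

    @property
    def true_volume_mm3(self) -> float:
        return float(sum(les.analytic_volume_mm3 for les in self.lesions))


@dataclass(frozen=True)
class ScannerConfig:
    """Capture-model parameters. Defaults mirror the profilometer raster
    (50 µm step-over, 2.6 µm repeatability) and a 0.2 mm intraoral remesh."""

    capture_model: str = "profilometer"  # profilometer | intraoral | ideal
    step_um: float = 50.0
    noise_sd_um: float = 2.6
    smoothing_iterations: int = 10
    smoothing_lambda: float = 0.5
    remesh_edge_mm: float | None = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.capture_model not in {"profilometer", "intraoral", "ideal"}:
            raise ValidationError(f"unknown capture model {self.capture_model!r}")
        if self.step_um <= 0:
            raise ValidationError("step_um must be positive")
        if self.noise_sd_um < 0 or self.smoothing_iterations < 0 or self.smoothing_lambda < 0:
            raise ValidationError("noise/smoothing parameters must be >= 0")


# --------------------------------------------------------------------------
# Crown generator
# --------------------------------------------------------------------------

def _ring_faces(inner: np.ndarray, outer: np.ndarray) -> np.ndarray:
    """Quad strip between two same-length closed vertex rings."""
    n = len(inner)
    j = np.arange(n)
    jn = (j + 1) % n
    t1 = np.column_stack([inner[j], outer[j], outer[jn]])
    t2 = np.column_stack([inner[j], outer[jn], inner[jn]])
    return np.concatenate([t1, t2])


def generate_crown(
    seed: int,
    size_mm: float = 10.0,
    cusp_count: int = 4,
    radial_segments: int = 40,
    angular_segments: int = 144,
    wall_segments: int = 30,
) -> SurfaceScan:
    """Deterministic crown-like surface: cusped occlusal dome on bulged walls.

    The occlusal footprint is a disc of radius ``0.35 * size_mm``; cusp bump
    amplitudes/positions are jittered by ``seed`` so crowns carry individual
    features. Walls bulge outward at mid-height on two opposite sides
    (labeled buccal at y > 0, lingual at y < 0), which creates undercuts
    under the bulge; the base ring is labeled "other". Canonical pose: the
    occlusal outward normal is approximately +z, base at z = 0.
    """
    rng = np.random.default_rng(seed)
    scale = size_mm / 10.0
    r_occ = 0.35 * size_mm
    h_wall = 4.0 * scale
    h_dome = 1.2 * scale
    bulge = 0.45 * scale

    n_th = angular_segments
    theta = np.arange(n_th) * (2.0 * np.pi / n_th)
    # mild low-order asymmetries (egg-shaped footprint, buccal bulge larger
    # than lingual) break the near-180-degree symmetry of the side walls so
    # rigid alignment has a unique basin
    rim_mod = 1.0 + 0.05 * np.cos(theta) + 0.02 * np.sin(theta)
    bulge_mod = np.sin(theta) ** 2 * (1.0 + 0.35 * np.sin(theta))

    # jittered cusp field
    cusp_angle = (
        np.deg2rad(45.0)
        + np.arange(cusp_count) * 2.0 * np.pi / cusp_count
        + np.deg2rad(rng.uniform(-10, 10, cusp_count))
    )
    cusp_radius = 0.55 * r_occ * (1.0 + rng.uniform(-0.12, 0.12, cusp_count))
    # demeaned amplitude jitter: cusps differ individually but their total
    # stays balanced, so the occlusal table is not tilted systematically
    amp_jit = rng.uniform(-0.25, 0.25, cusp_count)
    amp_jit -= amp_jit.mean()
    cusp_amp = 0.65 * scale * (1.0 + amp_jit)
    cusp_sigma = 0.80 * scale * (1.0 + rng.uniform(-0.15, 0.15, cusp_count))
    cx = cusp_radius * np.cos(cusp_angle)
    cy = cusp_radius * np.sin(cusp_angle)

    def occlusal_z(x, y):
        r2 = x * x + y * y
        # normalize by the angle-local rim radius so the dome vanishes at the
        # rim everywhere and the egg-shape does not tilt the occlusal table
        ang = np.arctan2(y, x)
        r_loc = r_occ * (1.0 + 0.05 * np.cos(ang) + 0.02 * np.sin(ang))
        z = h_wall + h_dome * (1.0 - r2 / (r_loc * r_loc))
        for k in range(cusp_count):
            d2 = (x - cx[k]) ** 2 + (y - cy[k]) ** 2
            z = z + cusp_amp[k] * np.exp(-d2 / (2.0 * cusp_sigma[k] ** 2))
        return z

    verts: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    faces: list[np.ndarray] = []

    # occlusal cap: center + radial rings
    verts.append(np.array([[0.0, 0.0, occlusal_z(0.0, 0.0)]]))
    labels.append(np.array(["occlusal"]))
    ring_index: list[np.ndarray] = []
    cursor = 1
    for i in range(1, radial_segments + 1):
        r = r_occ * rim_mod * i / radial_segments
        x = r * np.cos(theta)
        y = r * np.sin(theta)
        verts.append(np.column_stack([x, y, occlusal_z(x, y)]))
        labels.append(np.full(n_th, "occlusal"))
        ring_index.append(np.arange(cursor, cursor + n_th))
        cursor += n_th
    # center fan
    first = ring_index[0]
    j = np.arange(n_th)
    faces.append(np.column_stack([np.zeros(n_th, np.int64), first[j], first[(j + 1) % n_th]]))
    for i in range(1, radial_segments):
        faces.append(_ring_faces(ring_index[i - 1], ring_index[i]))

    # walls: rim ring -> base, with mid-height bulge on +-y sides
    rim = ring_index[-1]
    r_rim = r_occ * rim_mod
    z_rim = occlusal_z(r_rim * np.cos(theta), r_rim * np.sin(theta))
    prev = rim
    for k in range(1, wall_segments + 1):
        t = k / wall_segments
        rho = r_rim + bulge * np.sin(np.pi * t) * bulge_mod
        x = rho * np.cos(theta)
        y = rho * np.sin(theta)
        z = z_rim * (1.0 - t)
        verts.append(np.column_stack([x, y, z]))
        if k == wall_segments:
            lab = np.full(n_th, "other")
        else:
            lab = np.where(np.sin(theta) >= 0, "buccal", "lingual").astype("<U8")
        labels.append(lab)
        row = np.arange(cursor, cursor + n_th)
        cursor += n_th
        faces.append(_ring_faces(prev, row))  # (upper_j, lower_j, lower_j+1) winds outward
        prev = row

    scan = SurfaceScan(
        np.concatenate(verts),
        np.concatenate(faces),
        np.concatenate(labels),
        provenance={"capture_model": "ideal", "timepoint": "baseline", "seed": int(seed),
                    "size_mm": float(size_mm), "occlusal_radius_mm": float(r_occ),
                    "construction_axis": (0.0, 0.0, 1.0)},
    )
    return scan


# --------------------------------------------------------------------------
# Wear fields
# --------------------------------------------------------------------------

def _occlusal_frame(scan: SurfaceScan):
    """(plane, origin, u, v) of the occlusal region, outward-oriented."""
    mask = scan.region_mask("occlusal")
    if not mask.any():
        raise ValidationError("scan has no occlusal region")
    vn = vertex_normals(scan)
    plane = fit_plane(scan.vertices[mask], orient_along=vn[mask].mean(axis=0))
    origin = plane.project(scan.vertices[mask].mean(axis=0))
    u, v = plane.basis()
    return plane, origin, u, v


def apply_wear(scan: SurfaceScan, lesions: LesionConfig, seed: int | None = None):
    """Displace occlusal vertices along the inward occlusal-plane normal.

    Returns ``(worn_scan, true_volume_mm3)``. The depth field is a function
    of in-plane position, so the removed volume equals the analytic integral
    of the field exactly; non-occlusal geometry is untouched bitwise.
    ``seed`` is accepted for interface uniformity (the field is deterministic).
    """
    plane, origin, u, v = _occlusal_frame(scan)
    mask = scan.region_mask("occlusal")
    rel = scan.vertices[mask] - origin
    pu = rel @ u
    pv = rel @ v

    footprint = float(np.sqrt(pu**2 + pv**2).max())
    for les in lesions.lesions:
        if np.hypot(*les.center) > footprint:
            raise ValidationError(
                f"lesion center {les.center} lies outside the occlusal footprint (r={footprint:.2f} mm)"
            )

    depth = np.zeros(mask.sum())
    for les in lesions.lesions:
        depth = depth + les.depth(pu, pv)

    # thickness guard: depth must not punch through toward the base ring
    base_mask = scan.region_mask("other")
    if base_mask.any():
        base_level = float((scan.vertices[base_mask] @ plane.normal).mean())
        allowance = scan.vertices[mask] @ plane.normal - base_level
        if np.any(depth > 0.8 * allowance):
            raise ValidationError("lesion deeper than the local crown thickness")

    worn = scan.copy()
    wv = worn.vertices.copy()
    wv[mask] -= depth[:, None] * plane.normal
    worn.vertices = wv
    worn.provenance = {**scan.provenance, "timepoint": "followup"}
    return worn, lesions.true_volume_mm3


def apply_reference_wear(
    scan: SurfaceScan,
    depth_um: float,
    regions: tuple[str, ...] = ("buccal",),
    patch_center_deg: float = 90.0,
    patch_sigma_deg: float = 22.0,
    band_center_frac: float = 0.8,
    band_sigma_mm: float = 0.6,
) -> SurfaceScan:
    """Localized smooth-surface wear patch on a side-wall reference region.

    Erodes labeled wall vertices inward along their normals by a Gaussian
    patch: angular window around ``patch_center_deg`` (atan2(y, x) in the
    canonical pose) times a height band centered at ``band_center_frac`` of
    the region's height range (near the occlusal margin by default). This
    models reference surfaces that are *not* perfectly unchanged between
    visits — exactly the situation that separates trimmed from untrimmed
    alignment; the patch is local so most of the reference stays intact.
    """
    if depth_um < 0:
        raise ValidationError("depth_um must be >= 0")
    if depth_um == 0:
        return scan.copy()
    mask = scan.region_mask(set(regions))
    if not mask.any():
        raise ValidationError(f"no vertices in regions {regions}")
    vn = vertex_normals(scan)
    z = scan.vertices[mask, 2]
    z0 = z.min() + band_center_frac * (z.max() - z.min())
    band = np.exp(-((z - z0) ** 2) / (2.0 * band_sigma_mm**2))
    ang = np.rad2deg(np.arctan2(scan.vertices[mask, 1], scan.vertices[mask, 0]))
    dang = (ang - patch_center_deg + 180.0) % 360.0 - 180.0
    window = np.exp(-(dang**2) / (2.0 * patch_sigma_deg**2))
    depth_mm = depth_um * 1e-3 * band * window
    out = scan.copy()
    wv = out.vertices.copy()
    wv[mask] -= depth_mm[:, None] * vn[mask]
    out.vertices = wv
    return out


# --------------------------------------------------------------------------
# Capture models
# --------------------------------------------------------------------------

def _transfer_labels(source: SurfaceScan, target_vertices: np.ndarray) -> np.ndarray:
    tree = cKDTree(source.vertices)
    _, idx = tree.query(target_vertices)
    return source.region_labels[idx]


def simulate_profilometer(scan: SurfaceScan, cfg: ScannerConfig) -> SurfaceScan:
    """Raster capture: top-most surface height on a ``step_um`` grid.

    The probe records a single z per (x, y) — undercut geometry disappears —
    then i.i.d. Gaussian z-noise with sd ``noise_sd_um`` is added and the
    grid is triangulated. Labels transfer from the nearest source vertex.
    """
    if cfg.capture_model != "profilometer":
        raise ValidationError("cfg.capture_model must be 'profilometer'")
    rng = np.random.default_rng(cfg.seed)
    step_mm = cfg.step_um * 1e-3
    lo = scan.vertices.min(axis=0)
    hi = scan.vertices.max(axis=0)
    xs = np.arange(lo[0], hi[0] + step_mm * 0.5, step_mm)
    ys = np.arange(lo[1], hi[1] + step_mm * 0.5, step_mm)
    xx, yy = np.meshgrid(xs, ys)
    origins = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
    soup = TriangleSoup(scan)
    t, valid = soup.ray_max(origins, np.array([0.0, 0.0, 1.0]))
    heights = np.where(valid, t, np.nan).reshape(xx.shape)
    heights = heights + rng.normal(0.0, cfg.noise_sd_um * 1e-3, size=heights.shape)
    grid = RasterGrid(cfg.step_um, cfg.step_um, heights, origin_mm=(float(xs[0]), float(ys[0])))
    out = grid_to_scan(grid)
    out.region_labels = _transfer_labels(scan, out.vertices)
    out.provenance = {**scan.provenance, "capture_model": "profilometer", "seed": cfg.seed}
    return out


def _vertex_cluster(scan: SurfaceScan, cell_mm: float) -> SurfaceScan:
    """Decimate by uniform vertex clustering (undercut-preserving remesh)."""
    key = np.floor(scan.vertices / cell_mm).astype(np.int64)
    uniq, inverse = np.unique(key, axis=0, return_inverse=True)
    n_new = len(uniq)
    sums = np.zeros((n_new, 3))
    np.add.at(sums, inverse, scan.vertices)
    counts = np.bincount(inverse, minlength=n_new).astype(float)
    new_verts = sums / counts[:, None]
    new_faces = inverse[scan.faces]
    ok = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    new_faces = new_faces[ok]
    # drop duplicate faces irrespective of winding
    sorted_f = np.sort(new_faces, axis=1)
    _, first = np.unique(sorted_f, axis=0, return_index=True)
    new_faces = new_faces[np.sort(first)]
    return SurfaceScan(new_verts, new_faces, provenance=dict(scan.provenance))


def _laplacian_smooth(vertices: np.ndarray, faces: np.ndarray, iterations: int, lam: float) -> np.ndarray:
    import scipy.sparse as sp

    n = len(vertices)
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    v = vertices.copy()
    for _ in range(iterations):
        mean_nbr = adj @ v / deg[:, None]
        v = v + lam * (mean_nbr - v)
    return v


def simulate_intraoral(scan: SurfaceScan, cfg: ScannerConfig) -> SurfaceScan:
    """Intraoral capture: coarse remesh + Laplacian smoothing + vertex noise.

    Undercuts survive (clustering keeps 3D structure); sharp topography is
    attenuated — the interpolation/averaging artifact under study. With
    remeshing disabled and zero smoothing/noise this is the identity.
    """
    if cfg.capture_model != "intraoral":
        raise ValidationError("cfg.capture_model must be 'intraoral'")
    rng = np.random.default_rng(cfg.seed)
    out = scan.copy()
    if cfg.remesh_edge_mm:
        out = _vertex_cluster(out, cfg.remesh_edge_mm)
    if cfg.smoothing_iterations > 0 and cfg.smoothing_lambda > 0:
        out.vertices = _laplacian_smooth(
            out.vertices, out.faces, cfg.smoothing_iterations, cfg.smoothing_lambda
        )
    if cfg.noise_sd_um > 0:
        out.vertices = out.vertices + rng.normal(0.0, cfg.noise_sd_um * 1e-3, out.vertices.shape)
    out.region_labels = _transfer_labels(scan, out.vertices)
    out.provenance = {**scan.provenance, "capture_model": "intraoral", "seed": cfg.seed}
    return out


def simulate_capture(scan: SurfaceScan, cfg: ScannerConfig) -> SurfaceScan:
    if cfg.capture_model == "ideal":
        out = scan.copy()
        out.provenance = {**scan.provenance, "capture_model": "ideal"}
        return out
    if cfg.capture_model == "profilometer":
        return simulate_profilometer(scan, cfg)
    return simulate_intraoral(scan, cfg)


# --------------------------------------------------------------------------
# Pose
# --------------------------------------------------------------------------

def perturb_pose(
    scan: SurfaceScan, max_angle_deg: float, max_translation_mm: float, seed: int
) -> tuple[SurfaceScan, RigidTransform]:
    """Apply a random rigid displacement; returns the exact transform used.

    Rotation: uniform random axis, angle uniform in [0, max_angle_deg];
    translation components uniform in [-max, +max]. Zero bounds give the
    identity.
    """
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle_deg) if max_angle_deg > 0 else 0.0
    trans = rng.uniform(-max_translation_mm, max_translation_mm, 3) if max_translation_mm > 0 else np.zeros(3)
    transform = RigidTransform.from_axis_angle(axis, angle, trans)
    return scan.transformed(transform), transform


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Distributional defaults for a synthetic study cohort.

    Lesion amplitudes are log-normal with a median chosen so per-surface
    true wear volume sits around 1 mm^3 — the same order as clinically
    reported erosive-wear medians. Reference (wall) wear is a shallow
    band so alignment reference surfaces are imperfect, as in vivo.
    """

    n_surfaces: int = 30
    crown_size_mm: float = 10.0
    crown_radial_segments: int = 40
    crown_angular_segments: int = 144
    crown_wall_segments: int = 30
    lesion_count_range: tuple[int, int] = (1, 3)
    lesion_amp_median_mm: float = 0.19
    lesion_amp_sigma_log: float = 0.5
    lesion_sigma_range_mm: tuple[float, float] = (0.5, 0.8)
    lesion_center_radius_mm: float = 1.0
    reference_wear_depth_um_range: tuple[float, float] = (30.0, 80.0)
    max_pose_angle_deg: float = 5.0
    max_pose_translation_mm: float = 2.0
    profilometer: ScannerConfig = field(
        default_factory=lambda: ScannerConfig(capture_model="profilometer")
    )
    intraoral: ScannerConfig = field(
        default_factory=lambda: ScannerConfig(capture_model="intraoral", noise_sd_um=5.0)
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_surfaces < 1:
            raise ValidationError("n_surfaces must be >= 1")


@dataclass
class ScanPairBundle:
    """All renderings of one synthetic surface.

    ``scans[(model, timepoint)]`` for model in {profilometer, intraoral} and
    timepoint in {baseline, followup}; follow-up scans share one pose offset.
    The ideal pair carries the ground truth.
    """

    surface_id: str
    scans: dict
    ideal_baseline: SurfaceScan
    ideal_followup: SurfaceScan
    true_volume_mm3: float
    true_transform: RigidTransform
    lesions: LesionConfig
    seed: int


def draw_lesions(rng: np.random.Generator, cfg: CohortConfig) -> LesionConfig:
    count = int(rng.integers(cfg.lesion_count_range[0], cfg.lesion_count_range[1] + 1))
    lesions = []
    for _ in range(count):
        r = cfg.lesion_center_radius_mm * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        amp = cfg.lesion_amp_median_mm * np.exp(rng.normal(0.0, cfg.lesion_amp_sigma_log))
        amp = float(np.clip(amp, 0.02, 0.8))
        sig = float(rng.uniform(*cfg.lesion_sigma_range_mm))
        lesions.append(
            Lesion(
                shape="gaussian",
                center=(float(r * np.cos(phi)), float(r * np.sin(phi))),
                amplitude_mm=amp,
                sigma_mm=sig,
            )
        )
    return LesionConfig(tuple(lesions))


def generate_cohort(cfg: CohortConfig):
    """Generate the cohort: list of :class:`ScanPairBundle` + ground-truth table.

    Fully deterministic given ``cfg.seed``. The ground-truth table columns:
    surface_id, true_volume_mm3, transform flattened row-major (t00..t23),
    lesion count, total lesion depth, and the per-surface seed.
    """
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_surfaces)
    bundles = []
    rows = []
    for i, child in enumerate(children):
        seeds = child.generate_state(8)
        rng = np.random.default_rng(child)
        surface_id = f"S{i:03d}"

        crown = generate_crown(
            int(seeds[0]) % (2**31),
            size_mm=cfg.crown_size_mm,
            radial_segments=cfg.crown_radial_segments,
            angular_segments=cfg.crown_angular_segments,
            wall_segments=cfg.crown_wall_segments,
        )
        lesions = draw_lesions(rng, cfg)
        worn, true_volume = apply_wear(crown, lesions)
        ref_lo, ref_hi = cfg.reference_wear_depth_um_range
        ref_depth = float(rng.uniform(ref_lo, ref_hi)) if ref_hi > 0 else 0.0
        if ref_depth > 0:
            # one erosion patch on the buccal wall, a shallower one lingually;
            # patches sit at mid-wall height, where the intraoral scan sees
            # them in full but the raster capture mostly cannot
            worn = apply_reference_wear(
                worn, ref_depth, regions=("buccal",),
                patch_center_deg=float(rng.uniform(70, 110)),
                band_center_frac=0.6,
            )
            worn = apply_reference_wear(
                worn, 0.6 * ref_depth, regions=("lingual",),
                patch_center_deg=float(rng.uniform(250, 290)),
                band_center_frac=0.6,
            )

        scans = {}
        pose: RigidTransform | None = None
        for mi, (model, base_cfg) in enumerate(
            (("profilometer", cfg.profilometer), ("intraoral", cfg.intraoral))
        ):
            for ti, (timepoint, ideal) in enumerate((("baseline", crown), ("followup", worn))):
                cap_cfg = replace(
                    base_cfg,
                    seed=int(seeds[3 + 2 * mi + ti]) % (2**31),
                )
                cap = simulate_capture(ideal, cap_cfg)
                cap.provenance["timepoint"] = timepoint
                if timepoint == "followup":
                    if pose is None:
                        cap, pose = perturb_pose(
                            cap, cfg.max_pose_angle_deg, cfg.max_pose_translation_mm,
                            int(seeds[2]) % (2**31),
                        )
                    else:
                        cap = cap.transformed(pose)
                scans[(model, timepoint)] = cap
        if pose is None:
            pose = RigidTransform.identity()

        bundles.append(
            ScanPairBundle(
                surface_id=surface_id,
                scans=scans,
                ideal_baseline=crown,
                ideal_followup=worn,
                true_volume_mm3=true_volume,
                true_transform=pose,
                lesions=lesions,
                seed=int(seeds[0]) % (2**31),
            )
        )
        row = {
            "surface_id": surface_id,
            "true_volume_mm3": true_volume,
            "n_lesions": len(lesions.lesions),
            "reference_wear_depth_um": ref_depth,
            "seed": int(seeds[0]) % (2**31),
        }
        for k, val in enumerate(pose.as_flat12()):
            row[f"t{k:02d}"] = val
        rows.append(row)
    return bundles, pd.DataFrame(rows)
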