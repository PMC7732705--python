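"""Wear outcome metrics from an aligned scan pair.

All measurements are taken perpendicular to the occlusal surface: one plane
is fitted to the baseline occlusal region and every baseline occlusal vertex
casts a bidirectional ray along that plane's outward normal into the aligned
follow-up surface. Negative signed distances are material loss.

Outputs follow the clinical reporting convention: volume change in mm^3
(loss negative), maximum point loss and mean profile loss in µm (positive
magnitudes).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_core import SurfaceScan, ValidationError, fit_plane, region_submesh, vertex_normals
from .mesh_core.spatial import TriangleSoup

__all__ = [
    "DistanceMap",
    "WearResult",
    "CoverageError",
    "occlusal_direction",
    "distance_map",
    "volume_change",
    "max_point_loss",
    "mean_profile_loss",
    "truncate_positive",
    "truncate_positive_vertexwise",
    "measure_pair",
]


class CoverageError(RuntimeError):
    """Raised when too few measurement rays hit the follow-up surface."""


@dataclass
class DistanceMap:
    """Per-occlusal-vertex signed distances (µm; negative = loss).

    ``area_mm2`` is the one-third (barycentric) vertex area of the baseline
    occlusal submesh *projected onto the measurement plane*, so that
    sum(d_i * A_i) integrates the depth field exactly. ``valid`` flags
    vertices whose measurement ray found the follow-up surface; invalid
    entries are excluded from every aggregate.
    """

    distance_um: np.ndarray
    area_mm2: np.ndarray
    valid: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        n = len(self.distance_um)
        if len(self.area_mm2) != n or len(self.valid) != n:
            raise ValidationError("distance/area/valid arrays must be equal length")
        if np.any(self.area_mm2 < 0):
            raise ValidationError("vertex areas must be >= 0")

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean()) if len(self.valid) else 0.0

    def valid_distances(self) -> np.ndarray:
        return self.distance_um[self.valid]

    def valid_areas(self) -> np.ndarray:
        return self.area_mm2[self.valid]


@dataclass
class WearResult:
    """One surface's outcome record for one (scanner, strategy) cell."""

    volume_change_mm3: float
    max_point_loss_um: float
    mean_profile_loss_um: float
    truncated_volume_mm3: float
    valid_fraction: float
    surface_id: str = ""
    scanner: str = ""
    software_strategy: str = ""

    def as_dict(self) -> dict:
        return {
            "surface_id": self.surface_id,
            "scanner": self.scanner,
            "strategy": self.software_strategy,
            "volume_change_mm3": self.volume_change_mm3,
            "max_point_loss_um": self.max_point_loss_um,
            "mean_profile_loss_um": self.mean_profile_loss_um,
            "truncated_volume_mm3": self.truncated_volume_mm3,
            "valid_fraction": self.valid_fraction,
        }


def occlusal_direction(baseline: SurfaceScan) -> np.ndarray:
    """Outward unit normal of the plane fitted to the occlusal region."""
    mask = baseline.region_mask("occlusal")
    if not mask.any():
        raise ValidationError("baseline has no occlusal region")
    vn = vertex_normals(baseline)
    plane = fit_plane(baseline.vertices[mask], orient_along=vn[mask].mean(axis=0))
    return plane.normal


def distance_map(
    baseline: SurfaceScan,
    aligned_followup: SurfaceScan,
    direction: np.ndarray | None = None,
    min_valid_fraction: float = 0.5,
) -> DistanceMap:
    """Signed perpendicular distances from baseline occlusal vertices to the
    aligned follow-up surface.

    Each baseline occlusal vertex casts a bidirectional ray along
    ``direction`` (default: the occlusal plane normal); the signed hit
    distance is negative when the follow-up lies below the baseline along
    the outward direction (loss). Misses are flagged invalid; below
    ``min_valid_fraction`` coverage a :class:`CoverageError` signals gross
    misalignment or clipping instead of silently imputing.
    """
    if direction is None:
        direction = occlusal_direction(baseline)
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-8:
        raise ValidationError("direction must be a unit vector")

    occ, parent_idx = region_submesh(baseline, {"occlusal"})
    soup = TriangleSoup(aligned_followup)
    t, _, valid = soup.ray_nearest(occ.vertices, direction)
    dist_um = np.where(valid, t, np.nan) * 1e3

    # one-third vertex areas of the occlusal faces, projected on the plane
    a, b, c = occ.triangle_corners()
    cross = np.cross(b - a, c - a)
    proj_area = 0.5 * np.abs(cross @ direction)
    areas = np.zeros(occ.n_vertices)
    for k in range(3):
        np.add.at(areas, occ.faces[:, k], proj_area / 3.0)

    dm = DistanceMap(dist_um, areas, valid, direction)
    if dm.valid_fraction < min_valid_fraction:
        raise CoverageError(
            f"only {dm.valid_fraction:.0%} of measurement rays hit the follow-up surface"
        )
    return dm


def volume_change(dm: DistanceMap) -> float:
    """Signed volume change in mm^3 (sum of d_i * A_i over valid vertices)."""
    if not dm.valid.any():
        raise ValidationError("distance map has no valid entries")
    if dm.valid_fraction < 0.5:
        raise CoverageError("valid fraction below 0.5; refusing to integrate")
    return float(np.sum(dm.valid_distances() * 1e-3 * dm.valid_areas()))


def max_point_loss(dm: DistanceMap) -> float:
    """Magnitude (µm) of the deepest single-point loss; 0 if nothing negative."""
    d = dm.valid_distances()
    if len(d) == 0:
        raise ValidationError("distance map has no valid entries")
    return float(-min(d.min(), 0.0))


def mean_profile_loss(dm: DistanceMap) -> float:
    """Mean |d| (µm) over loss vertices only (d < 0); 0 when none are negative.

    Averaging over loss points (not the whole surface) matches the reporting
    convention in which profile-loss magnitudes far exceed volume-per-area.
    An all-vertex average is available via ``loss_only=False`` paths upstream.
    """
    d = dm.valid_distances()
    if len(d) == 0:
        raise ValidationError("distance map has no valid entries")
    neg = d[d < 0]
    return float(-neg.mean()) if len(neg) else 0.0


def truncate_positive(volumes_mm3) -> np.ndarray:
    """Per-surface truncation: positive volume changes (gain/error) set to 0."""
    v = np.asarray(volumes_mm3, dtype=float)
    return np.minimum(v, 0.0)


def truncate_positive_vertexwise(dm: DistanceMap) -> float:
    """Per-vertex truncation variant: positive distances zeroed before
    integration (labeled alternative for sensitivity analysis)."""
    if not dm.valid.any():
        raise ValidationError("distance map has no valid entries")
    d = np.minimum(dm.valid_distances(), 0.0)
    return float(np.sum(d * 1e-3 * dm.valid_areas()))


def measure_pair(
    baseline: SurfaceScan,
    aligned_followup: SurfaceScan,
    surface_id: str = "",
    scanner: str = "",
    software_strategy: str = "",
) -> tuple[WearResult, DistanceMap]:
    """Compute the full outcome record for one aligned pair."""
    dm = distance_map(baseline, aligned_followup)
    vol = volume_change(dm)
    result = WearResult(
        volume_change_mm3=vol,
        max_point_loss_um=max_point_loss(dm),
        mean_profile_loss_um=mean_profile_loss(dm),
        truncated_volume_mm3=float(truncate_positive([vol])[0]),
        valid_fraction=dm.valid_fraction,
        surface_id=surface_id,
        scanner=scanner,
        software_strategy=software_strategy,
    )
    return result, dm
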