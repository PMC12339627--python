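"""Geometric fundus parameters from landmark annotations.

Six parameters are derived from a :class:`~fundusquant.io.LandmarkSet`:

* ``ST_RA``, ``IT_RA``, ``ST_VA``, ``IT_VA`` — the supratemporal and
  infratemporal retinal artery/vein angles, measured as the unsigned angle
  (degrees, in [0, 180]) between the temporal horizontal ray from the optic
  disc center and the ray from the disc center to the annotated vessel
  crossing point;
* ``PMP`` — the papillomacular position, the signed angle between the
  temporal horizontal and the disc-center-to-fovea line, positive when the
  fovea lies inferior to (below) the horizontal through the disc center;
* ``ovality_ratio`` — maximum over minimum optic-disc diameter, where the
  diameters are the caliper (Feret) widths of the convex hull of the disc
  boundary annotation.

All coordinates are raster pixels (y grows downward, superior retina at
smaller y). The temporal horizontal is the horizontal ray from the disc
center toward the side the fovea is on, so right and left eyes share one
code path without image flipping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .exceptions import DegenerateGeometryError, ValidationError
from .io import LandmarkSet, _hull_or_error

__all__ = [
    "DiscGeometry",
    "GeometryParams",
    "fit_disc_geometry",
    "temporal_axis",
    "vessel_angle",
    "papillomacular_position",
    "compute_geometry",
]


@dataclass(frozen=True)
class DiscGeometry:
    """Optic-disc center and caliper diameters (pixels)."""

    center: np.ndarray  # (2,)
    d_max: float
    d_min: float

    @property
    def mean_radius(self) -> float:
        """(d_max + d_min) / 4 — the mean disc radius used to scale sampling circles."""
        return (self.d_max + self.d_min) / 4.0

    @property
    def ovality_ratio(self) -> float:
        return self.d_max / self.d_min


@dataclass(frozen=True)
class GeometryParams:
    ST_RA: float
    IT_RA: float
    ST_VA: float
    IT_VA: float
    PMP: float
    ovality_ratio: float

    def as_dict(self) -> dict[str, float]:
        return {
            "ST_RA": self.ST_RA,
            "IT_RA": self.IT_RA,
            "ST_VA": self.ST_VA,
            "IT_VA": self.IT_VA,
            "PMP": self.PMP,
            "ovality_ratio": self.ovality_ratio,
        }


def _polygon_centroid(vertices: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon given by ordered vertices."""
    x, y = vertices[:, 0], vertices[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return np.array([cx, cy])


def _min_caliper_width(hull_vertices: np.ndarray) -> float:
    # rotating-calipers fact: the minimum width is attained with one hull
    # edge flush against the caliper, so scan edges
    n = len(hull_vertices)
    best = np.inf
    for i in range(n):
        p, q = hull_vertices[i], hull_vertices[(i + 1) % n]
        edge = q - p
        norm = np.hypot(*edge)
        if norm == 0.0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        width = np.max(np.abs((hull_vertices - p) @ normal))
        best = min(best, width)
    return float(best)


def fit_disc_geometry(boundary: np.ndarray) -> DiscGeometry:
    """Fit disc center and caliper (Feret) diameters to boundary points.

    The center is the area centroid of the convex hull of the annotated
    boundary (robust to uneven annotation density); ``d_max`` is the maximum
    pairwise distance between hull vertices and ``d_min`` the minimum
    caliper width.
    """
    boundary = np.asarray(boundary, dtype=float)
    if boundary.ndim != 2 or boundary.shape[1] != 2:
        raise ValidationError("boundary must be an (n, 2) array")
    if len(boundary) < 5:
        raise ValidationError(f"need >= 5 boundary points, got {len(boundary)}")
    hull: ConvexHull = _hull_or_error(boundary, "disc boundary")
    verts = boundary[hull.vertices]
    diffs = verts[:, None, :] - verts[None, :, :]
    d_max = float(np.sqrt((diffs ** 2).sum(-1)).max())
    d_min = _min_caliper_width(verts)
    if d_min <= 0.0:
        raise ValidationError("disc boundary is degenerate (zero minimum width)")
    return DiscGeometry(center=_polygon_centroid(verts), d_max=d_max, d_min=d_min)


def temporal_axis(disc: DiscGeometry, fovea: np.ndarray) -> np.ndarray:
    """Unit vector of the temporal horizontal: (+1, 0) or (-1, 0).

    The sign follows the fovea's side of the disc, so the same convention
    covers right and left eyes.
    """
    fovea = np.asarray(fovea, dtype=float)
    dx = fovea[0] - disc.center[0]
    if dx == 0.0:
        raise DegenerateGeometryError(
            "fovea lies directly above/below the disc center; temporal direction undefined"
        )
    return np.array([np.sign(dx), 0.0])


def vessel_angle(disc: DiscGeometry, crossing: np.ndarray, temporal: np.ndarray) -> float:
    """Unsigned angle (degrees, [0, 180]) between the temporal ray and the
    ray from the disc center to the vessel crossing point."""
    v = np.asarray(crossing, dtype=float) - disc.center
    norm = np.hypot(*v)
    if norm == 0.0:
        raise DegenerateGeometryError("crossing point coincides with the disc center")
    cosang = np.clip(np.dot(v, temporal) / norm, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def papillomacular_position(
    disc: DiscGeometry, fovea: np.ndarray, temporal: np.ndarray
) -> float:
    """Signed papillomacular angle (degrees).

    Positive when the fovea lies inferior to (larger y than) the horizontal
    through the disc center, negative when superior.
    """
    v = np.asarray(fovea, dtype=float) - disc.center
    if np.hypot(*v) == 0.0:
        raise DegenerateGeometryError("fovea coincides with the disc center")
    # project onto the temporal direction so left/right eyes agree in sign
    return float(np.degrees(np.arctan2(v[1], temporal[0] * v[0])))


_ANGLE_FIELDS = {  # feature name -> crossing key
    "ST_RA": "ST_artery",
    "IT_RA": "IT_artery",
    "ST_VA": "ST_vein",
    "IT_VA": "IT_vein",
}


def compute_geometry(landmarks: LandmarkSet) -> GeometryParams:
    """Assemble the six geometric parameters from a landmark set."""
    disc = fit_disc_geometry(landmarks.disc_boundary)
    temporal = temporal_axis(disc, landmarks.fovea)
    angles: dict[str, float] = {}
    for feature, key in _ANGLE_FIELDS.items():
        try:
            angles[feature] = vessel_angle(disc, landmarks.crossings[key], temporal)
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(f"{key}: {exc}") from exc
    pmp = papillomacular_position(disc, landmarks.fovea, temporal)
    return GeometryParams(
        ST_RA=angles["ST_RA"],
        IT_RA=angles["IT_RA"],
        ST_VA=angles["ST_VA"],
        IT_VA=angles["IT_VA"],
        PMP=pmp,
        ovality_ratio=disc.ovality_ratio,
    )
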