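"""Colour fundus parameters: sampling circles, mean RGB, tessellation index.

Mean red/green/blue channel intensities are measured inside nine circles:
eight peripapillary circles placed at 45-degree steps on a ring around the
optic disc (starting temporal and proceeding through superior:
T, ST, S, SN, N, IN, I, IT) plus one circle centred on the fovea. The
tessellation fundus index at each location is

    TFI = R / (R + G + B)

computed from the mean channel intensities; larger TFI means a redder,
more tessellated (tigroid) fundus where choroidal vessels show through.

Circle geometry scales with the eye: ring centres sit at
``ring_distance_factor`` x mean disc radius from the disc centre, and each
circle's radius is ``circle_radius_factor`` x mean disc radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, EmptyRegionError, ValidationError
from .geometry import DiscGeometry, compute_geometry, fit_disc_geometry, temporal_axis
from .io import FEATURE_NAMES, FundusImage, LandmarkSet, LOCATIONS

__all__ = [
    "SamplingConfig",
    "PERIPAPILLARY_LOCATIONS",
    "sampling_centers",
    "mean_rgb_in_circle",
    "tessellation_index",
    "extract_features",
]

#: the eight ring locations, ordered temporal -> superior -> nasal -> inferior
PERIPAPILLARY_LOCATIONS = LOCATIONS[:-1]


@dataclass(frozen=True)
class SamplingConfig:
    """Dimensions of the nine sampling circles, as multiples of the mean disc radius."""

    ring_distance_factor: float = 2.0
    circle_radius_factor: float = 0.6

    def __post_init__(self) -> None:
        if self.ring_distance_factor <= 0 or self.circle_radius_factor <= 0:
            raise ValidationError("sampling factors must be positive")
        if self.ring_distance_factor <= 1.0 + self.circle_radius_factor:
            raise ValidationError(
                "ring_distance_factor must exceed 1 + circle_radius_factor "
                "so sampling circles clear the optic disc"
            )


def sampling_centers(
    disc: DiscGeometry, temporal: np.ndarray, cfg: SamplingConfig | None = None
) -> dict[str, np.ndarray]:
    """Centres of the eight peripapillary circles.

    Location k sits at angle 45 k degrees from the temporal direction,
    rotating through superior (smaller y) first; a left eye (temporal
    pointing -x) therefore yields the horizontal mirror of a right eye.
    """
    cfg = cfg or SamplingConfig()
    dist = cfg.ring_distance_factor * disc.mean_radius
    s = float(temporal[0])
    centers: dict[str, np.ndarray] = {}
    for k, loc in enumerate(PERIPAPILLARY_LOCATIONS):
        theta = np.radians(45.0 * k)
        # y-down raster coordinates: superior = negative y
        direction = np.array([s * np.cos(theta), -np.sin(theta)])
        centers[loc] = disc.center + dist * direction
    return centers


def mean_rgb_in_circle(
    image: FundusImage, center: np.ndarray, radius: float
) -> tuple[float, float, float]:
    """Per-channel mean over pixels whose centre lies within *radius* of *center*.

    Pixels outside the image are excluded (a 45-degree photograph can clip
    the nasal ring); a circle entirely outside the image raises
    :class:`EmptyRegionError`.
    """
    if radius < 1.0:
        raise ValidationError(f"sampling radius must be >= 1 px, got {radius}")
    cx, cy = float(center[0]), float(center[1])
    x0 = max(int(np.floor(cx - radius)), 0)
    x1 = min(int(np.ceil(cx + radius)), image.width - 1)
    y0 = max(int(np.floor(cy - radius)), 0)
    y1 = min(int(np.ceil(cy + radius)), image.height - 1)
    if x0 > x1 or y0 > y1:
        raise EmptyRegionError("sampling circle lies entirely outside the image")
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius ** 2
    if not mask.any():
        raise EmptyRegionError("sampling circle contains no pixel centres inside the image")
    patch = image.pixels[y0 : y1 + 1, x0 : x1 + 1][mask]
    means = patch.mean(axis=0, dtype=np.float64)
    return float(means[0]), float(means[1]), float(means[2])


def tessellation_index(r_mean: float, g_mean: float, b_mean: float) -> float:
    """Tessellation fundus index: R / (R + G + B) of the mean intensities."""
    total = r_mean + g_mean + b_mean
    if total <= 0:
        raise DegenerateInputError("TFI undefined: mean R + G + B is zero")
    return r_mean / total


def extract_features(
    image: FundusImage, landmarks: LandmarkSet, cfg: SamplingConfig | None = None
) -> pd.Series:
    """Compute the full 42-parameter feature vector for one eye.

    Returns a Series indexed by the canonical feature names: six geometric
    parameters followed by R/G/B/TFI blocks at the nine locations (the
    foveal circle is centred on the fovea landmark with the same radius as
    the peripapillary circles).
    """
    cfg = cfg or SamplingConfig()
    geo = compute_geometry(landmarks)
    disc = fit_disc_geometry(landmarks.disc_boundary)
    temporal = temporal_axis(disc, landmarks.fovea)
    centers = sampling_centers(disc, temporal, cfg)
    centers["fovea"] = np.asarray(landmarks.fovea, dtype=float)
    radius = cfg.circle_radius_factor * disc.mean_radius

    values = dict(geo.as_dict())
    for loc in LOCATIONS:
        try:
            r, g, b = mean_rgb_in_circle(image, centers[loc], radius)
        except EmptyRegionError as exc:
            raise EmptyRegionError(f"sampling circle {loc!r}: {exc}") from exc
        values[f"R_{loc}"] = r
        values[f"G_{loc}"] = g
        values[f"B_{loc}"] = b
        values[f"TFI_{loc}"] = tessellation_index(r, g, b)
    return pd.Series([values[name] for name in FEATURE_NAMES], index=list(FEATURE_NAMES))
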