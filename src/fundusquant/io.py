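"""Data model and readers/writers for fundus images, landmarks and feature tables.

The package works with three kinds of input:

* colour fundus photographs — 8-bit RGB PNG or TIFF (:class:`FundusImage`);
* per-eye manual landmark annotations — one JSON document per eye giving the
  fovea, the optic-disc boundary and four vessel crossing points
  (:class:`LandmarkSet`);
* feature tables — CSV with one row per eye holding the 42 quantitative
  fundus parameters plus optional refractive-error (RE, diopters) and
  axial-length (AL, mm) labels.

Pixel coordinates follow raster convention: origin at the top-left corner,
x increases rightward (columns), y increases downward (rows), 0-based.
Images are assumed to be oriented "superior is up" (superior retina at
smaller y); the orientation tag on :class:`LandmarkSet` makes that explicit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .exceptions import FormatError, SchemaError, ValidationError

__all__ = [
    "FundusImage",
    "LandmarkSet",
    "CROSSING_KEYS",
    "LOCATIONS",
    "GEOMETRY_FEATURES",
    "FEATURE_NAMES",
    "LABEL_COLUMNS",
    "load_image",
    "write_image",
    "read_landmarks",
    "write_landmarks",
    "read_feature_table",
    "write_feature_table",
    "validate_feature_table",
]

#: vessel crossing-point keys, fixed order
CROSSING_KEYS = ("ST_artery", "IT_artery", "ST_vein", "IT_vein")

#: colour sampling locations: eight peripapillary compass positions plus the fovea
LOCATIONS = ("T", "ST", "S", "SN", "N", "IN", "I", "IT", "fovea")

#: the six geometric parameters
GEOMETRY_FEATURES = ("ST_RA", "IT_RA", "ST_VA", "IT_VA", "PMP", "ovality_ratio")

#: canonical order of the 42 fundus parameters
FEATURE_NAMES = GEOMETRY_FEATURES + tuple(
    f"{channel}_{loc}" for channel in ("R", "G", "B", "TFI") for loc in LOCATIONS
)

#: optional outcome labels, in canonical trailing order
LABEL_COLUMNS = ("RE", "AL")

MIN_IMAGE_SIDE = 64


@dataclass
class FundusImage:
    """An 8-bit RGB fundus photograph held as an H x W x 3 uint8 array."""

    pixels: np.ndarray
    source_path: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(
                f"expected a 3-channel RGB image, got array of shape {px.shape}"
            )
        if px.dtype != np.uint8:
            raise FormatError(f"expected 8-bit channels, got dtype {px.dtype}")
        if px.shape[0] < MIN_IMAGE_SIDE or px.shape[1] < MIN_IMAGE_SIDE:
            raise ValidationError(
                f"image must be at least {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE} px, "
                f"got {px.shape[1]}x{px.shape[0]}"
            )
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def load_image(path: str | Path) -> FundusImage:
    """Load an 8-bit RGB PNG/TIFF fundus photograph.

    Grayscale or 16-bit inputs are rejected with :class:`FormatError` rather
    than silently converted.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # decoder failure
        raise IOError(f"could not decode image {path}: {exc}") from exc
    if arr.ndim == 2:
        raise FormatError(f"{path}: grayscale image, expected 3-channel RGB")
    if arr.ndim != 3 or arr.shape[2] != 3:
        nchan = arr.shape[2] if arr.ndim == 3 else 1
        raise FormatError(f"{path}: expected 3 channels, got {nchan}")
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit channels, got dtype {arr.dtype}")
    return FundusImage(pixels=arr, source_path=str(path))


def write_image(image: FundusImage, path: str | Path) -> None:
    """Write an image to PNG or TIFF (chosen by extension); lossless."""
    iio.imwrite(Path(path), image.pixels)


def _hull_or_error(points: np.ndarray, what: str) -> ConvexHull:
    try:
        return ConvexHull(points)
    except QhullError as exc:
        raise ValidationError(f"{what}: points are collinear or degenerate") from exc


def point_outside_hull(point: np.ndarray, hull: ConvexHull, tol: float = 1e-9) -> bool:
    """True if *point* lies strictly outside the convex hull."""
    p = np.asarray(point, dtype=float)
    return bool(np.any(hull.equations[:, :2] @ p + hull.equations[:, 2] > tol))


@dataclass
class LandmarkSet:
    """Per-eye manual annotations, all in pixel coordinates.

    Invariants (checked by :meth:`validate`): the disc boundary has at least
    five non-collinear points; the fovea and every vessel crossing point lie
    strictly outside the convex hull of the disc boundary.
    """

    eye_id: str
    eye_side: str  # "right" | "left"
    fovea: np.ndarray  # (2,)
    disc_boundary: np.ndarray  # (n, 2), n >= 5
    crossings: dict[str, np.ndarray]  # keys = CROSSING_KEYS
    orientation: str = "superior_is_up"

    def __post_init__(self) -> None:
        self.fovea = np.asarray(self.fovea, dtype=float)
        self.disc_boundary = np.asarray(self.disc_boundary, dtype=float)
        self.crossings = {k: np.asarray(v, dtype=float) for k, v in self.crossings.items()}
        self.validate()

    def validate(self) -> None:
        if self.eye_side not in ("right", "left"):
            raise ValidationError(f"eye_side must be 'right' or 'left', got {self.eye_side!r}")
        if self.orientation != "superior_is_up":
            raise ValidationError(f"unsupported orientation {self.orientation!r}")
        missing = [k for k in CROSSING_KEYS if k not in self.crossings]
        if missing:
            raise SchemaError(f"missing crossing point(s): {', '.join(missing)}")
        if self.disc_boundary.ndim != 2 or self.disc_boundary.shape[1] != 2:
            raise ValidationError("disc_boundary must be an (n, 2) array of points")
        if len(self.disc_boundary) < 5:
            raise ValidationError(
                f"disc_boundary needs >= 5 points, got {len(self.disc_boundary)}"
            )
        hull = _hull_or_error(self.disc_boundary, "disc_boundary")
        if not point_outside_hull(self.fovea, hull):
            raise ValidationError("fovea inside disc: fovea must lie outside the disc boundary")
        for key in CROSSING_KEYS:
            if not point_outside_hull(self.crossings[key], hull):
                raise ValidationError(
                    f"crossing point {key} lies inside the disc boundary"
                )


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a per-eye landmark annotation JSON file."""
    path = Path(path)
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    for key in ("eye_id", "eye_side", "fovea", "disc_boundary", "crossings"):
        if key not in doc:
            raise SchemaError(f"{path}: missing required key {key!r}")
    crossings = doc["crossings"]
    if not isinstance(crossings, dict):
        raise SchemaError(f"{path}: 'crossings' must be an object")
    missing = [k for k in CROSSING_KEYS if k not in crossings]
    if missing:
        raise SchemaError(f"{path}: missing crossing key(s): {', '.join(missing)}")
    return LandmarkSet(
        eye_id=str(doc["eye_id"]),
        eye_side=str(doc["eye_side"]),
        fovea=np.asarray(doc["fovea"], dtype=float),
        disc_boundary=np.asarray(doc["disc_boundary"], dtype=float),
        crossings={k: np.asarray(crossings[k], dtype=float) for k in CROSSING_KEYS},
        orientation=doc.get("orientation", "superior_is_up"),
    )


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    doc = {
        "eye_id": landmarks.eye_id,
        "eye_side": landmarks.eye_side,
        "orientation": landmarks.orientation,
        "fovea": [float(v) for v in landmarks.fovea],
        "disc_boundary": [[float(x), float(y)] for x, y in landmarks.disc_boundary],
        "crossings": {
            k: [float(v) for v in landmarks.crossings[k]] for k in CROSSING_KEYS
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check column set/order and eye_id uniqueness of a feature table."""
    cols = list(table.columns)
    expected = ["eye_id", *FEATURE_NAMES]
    if cols[: len(expected)] != expected:
        for want, got in zip(expected, cols + [None] * len(expected)):
            if want != got:
                raise SchemaError(
                    f"feature table columns out of order: expected {want!r}, got {got!r}"
                )
    extras = cols[len(expected):]
    allowed_tails = [[], ["RE"], ["AL"], ["RE", "AL"]]
    if extras not in allowed_tails:
        raise SchemaError(
            f"unexpected trailing columns {extras!r}; only RE, AL labels allowed"
        )
    dup = table["eye_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate eye_id(s): {sorted(table.loc[dup, 'eye_id'].unique())}"
        )
    return table


def feature_table_columns(labels: bool = True) -> list[str]:
    """Canonical column order of a feature table CSV."""
    cols = ["eye_id", *FEATURE_NAMES]
    if labels:
        cols += list(LABEL_COLUMNS)
    return cols


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table CSV in canonical column order (>= 10 significant digits)."""
    validate_feature_table(table)
    table.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a feature table CSV."""
    table = pd.read_csv(path, dtype={"eye_id": str})
    return validate_feature_table(table)
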