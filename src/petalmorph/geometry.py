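"""Cell-shape statistics for petal epidermis outlines.

Pavement cells of a differentiated petal epidermis are "jigsaw-puzzle"
shaped: their anticlinal walls form lobes and indentations.  The degree of
lobing is quantified through the *solidity* of the cell outline,

    S = area(polygon) / area(convex hull),    S in (0, 1],

and *cell lobeyness* CL = 1 - S, so a cell with regular (convex) walls has
CL = 0 and a strongly lobed cell approaches 1.  Cell area (CA, um^2) and the
cell length-to-width ratio (CLWR: maximal extent along the petal's
longitudinal axis over the maximal perpendicular extent) complete the
per-cell description.  Positions of images along the petal midrib are
standardized to PAMR in [0, 1], 0 = basal end, 1 = apical end.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

logger = logging.getLogger(__name__)

__all__ = [
    "Polygon",
    "CellRecord",
    "ImageSample",
    "PetalSample",
    "polygon_area",
    "lobeyness",
    "clwr",
    "sample_cells",
    "standardize_pamr",
    "estimate_cell_number",
]


class GeometryError(ValueError):
    """Invalid polygon or degenerate geometric configuration."""


@dataclass
class Polygon:
    """Ordered planar cell outline in micrometres.

    ``longitudinal_axis`` names the coordinate axis aligned with the petal
    midrib ("y" by default: images are oriented crops, so the axis is
    declared, never inferred from the shape).
    """

    vertices: np.ndarray  # (n, 2) float array
    longitudinal_axis: str = "y"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise GeometryError("polygon needs >= 3 two-dimensional vertices")
        if not np.all(np.isfinite(v)):
            raise GeometryError("polygon vertices must be finite")
        self.vertices = v
        if self.longitudinal_axis not in ("x", "y"):
            raise GeometryError(
                f"longitudinal_axis must be 'x' or 'y', got {self.longitudinal_axis!r}"
            )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def validate_simple(self) -> None:
        """Reject self-intersecting outlines (digitization faults are not
        silently repaired)."""
        from shapely.geometry import Polygon as ShapelyPolygon

        if not ShapelyPolygon(self.vertices).is_valid:
            raise GeometryError("polygon is self-intersecting or degenerate")


@dataclass
class CellRecord:
    """One measured cell with its design covariates."""

    species: str
    stage: str  # "bud" | "mature"
    individual: str
    image_index: int
    pamr: float
    cell_id: str
    cl: float
    ca: float
    clwr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pamr <= 1.0):
            raise ValueError(f"pamr must lie in [0, 1], got {self.pamr}")
        if not (0.0 <= self.cl < 1.0):
            raise ValueError(f"cl must lie in [0, 1), got {self.cl}")
        if self.ca <= 0:
            raise ValueError("ca must be positive")
        if self.clwr <= 0:
            raise ValueError("clwr must be positive")


@dataclass
class ImageSample:
    """One SEM image: its area, total cell count and member outlines."""

    area: float
    cell_count: int
    pamr: float
    polygons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("image area must be positive")
        if self.cell_count < 0:
            raise ValueError("cell count must be non-negative")


@dataclass
class PetalSample:
    """A petal cut in two halves, imaged at several midrib positions."""

    half_area_1: float
    half_area_2: float
    images: list = field(default_factory=list)

    @property
    def total_area(self) -> float:
        return self.half_area_1 + self.half_area_2


def _closed(vertices: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    if np.allclose(v[0], v[-1]):
        v = v[:-1]
    return v


def polygon_area(poly: Polygon) -> float:
    """Absolute enclosed (shoelace) area, independent of winding direction."""
    v = _closed(poly.vertices)
    if len(v) < 3:
        raise GeometryError("polygon needs >= 3 distinct vertices")
    v = v - v.mean(axis=0)  # centering avoids cancellation far from the origin
    x, y = v[:, 0], v[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area <= 0:
        raise GeometryError("polygon encloses zero area")
    return float(area)


def _hull_area(vertices: np.ndarray) -> float:
    vertices = vertices - vertices.mean(axis=0)
    try:
        hull = ConvexHull(vertices)
    except QhullError as exc:  # collinear input
        raise GeometryError("degenerate convex hull") from exc
    return float(hull.volume)  # 2-D: "volume" is the area


def lobeyness(poly: Polygon) -> tuple[float, float]:
    """Solidity S = area / hull area and cell lobeyness CL = 1 - S.

    Convex outlines give CL = 0 up to numerical round-off; small negative
    round-off is clamped to exactly 0.
    """
    area = polygon_area(poly)
    hull = _hull_area(_closed(poly.vertices))
    s = area / hull
    s = min(s, 1.0)
    cl = 1.0 - s
    if cl < 1e-12:
        cl = 0.0
    return float(s), float(cl)


def clwr(poly: Polygon) -> float:
    """Length-to-width ratio: maximal extent along the declared longitudinal
    axis over the maximal perpendicular extent."""
    v = _closed(poly.vertices)
    ext = v.max(axis=0) - v.min(axis=0)
    if poly.longitudinal_axis == "y":
        length, width = ext[1], ext[0]
    else:
        length, width = ext[0], ext[1]
    if width <= 0:
        raise GeometryError("zero extent perpendicular to the longitudinal axis")
    if length <= 0:
        raise GeometryError("zero extent along the longitudinal axis")
    return float(length / width)


def sample_cells(image: ImageSample, n: int = 10, seed=None) -> list:
    """Draw ``n`` distinct cell outlines uniformly without replacement.

    Mirrors the measurement protocol of choosing 10 cells per SEM image.  If
    the image holds fewer than ``n`` outlines, all are returned and a
    warning is logged.
    """
    if not image.polygons:
        raise GeometryError("image contains no cell outlines")
    rng = np.random.default_rng(seed)
    if len(image.polygons) <= n:
        if len(image.polygons) < n:
            msg = (
                f"requested {n} cells but image holds only "
                f"{len(image.polygons)}; returning all"
            )
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
        return list(image.polygons)
    idx = rng.choice(len(image.polygons), size=n, replace=False)
    return [image.polygons[i] for i in sorted(idx)]


def standardize_pamr(image_index: int, n_images: int, orientation: str = "basal_first") -> float:
    """Standardized position along the petal midrib for image ``image_index``
    (1-based) of ``n_images`` equally spaced images.

    The basal end maps to 0 and the apical end to 1 regardless of the
    acquisition order: ``basal_first`` means image 1 was taken at the base,
    ``apical_first`` that image 1 was taken at the apex.
    """
    if n_images < 2:
        raise ValueError("need at least 2 images to standardize positions")
    if not (1 <= image_index <= n_images):
        raise ValueError(f"image_index {image_index} outside 1..{n_images}")
    if orientation not in ("basal_first", "apical_first"):
        raise ValueError(f"unknown orientation {orientation!r}")
    p = (image_index - 1) / (n_images - 1)
    if orientation == "apical_first":
        p = 1.0 - p
    return float(p)


def estimate_cell_number(images: list, petal_area: float) -> tuple[float, float]:
    """Estimate the total epidermal cell number of a petal.

    Each SEM image yields an estimate (cells counted / image area) x petal
    area; the function returns the arithmetic mean over images and its
    standard error (sample sd / sqrt(n)).
    """
    if petal_area <= 0:
        raise ValueError("petal area must be positive")
    if len(images) < 2:
        raise ValueError("need >= 2 images (standard error undefined for one)")
    estimates = np.array([img.cell_count / img.area * petal_area for img in images])
    mean = float(estimates.mean())
    se = float(estimates.std(ddof=1) / np.sqrt(len(estimates)))
    return mean, se
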