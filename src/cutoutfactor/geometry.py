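"""Cutout aperture geometry: polygons, binary raster masks, and P2A complexity.

Cutout apertures are simple closed polygons in the cutout plane, in cm, with
y up and the origin at the cone center.  Rasterization produces the binary
aperture function f[x, y] (1 = open, 0 = blocked) that the output kernel is
convolved with.  The perimeter-squared-over-area ratio (P2A) quantifies shape
complexity; it is 4*pi for a circle and grows with irregularity, and values
above ~30 indicate shapes whose predicted relative output distributions
should be treated with caution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon

__all__ = [
    "CutoutShape",
    "ApertureMask",
    "rasterize",
    "compute_p2a",
    "classify_complexity",
    "P2A_CIRCLE",
    "DEFAULT_P2A_CUTOFF",
]

#: Isoperimetric lower bound: P2A of a circle.
P2A_CIRCLE = 4.0 * math.pi

#: Complexity cutoff above which relative-dosimetry predictions get a caution flag.
DEFAULT_P2A_CUTOFF = 30.0


@dataclass
class CutoutShape:
    """Simple closed polygon describing a cutout aperture.

    ``vertices`` is an (N, 2) array of (x_cm, y_cm) points, implicitly closed.
    The polygon must be simple (non-self-intersecting) with positive area;
    multi-hole apertures are rejected.
    """

    vertices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array of (x_cm, y_cm)")
        if v.shape[0] < 3:
            raise ValueError("degenerate polygon: need at least 3 vertices")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertices must be finite")
        poly = Polygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("degenerate polygon: self-intersecting or zero area")
        self.vertices = v

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_cm2(self) -> float:
        return float(self.polygon.area)

    @property
    def perimeter_cm(self) -> float:
        return float(self.polygon.length)


@dataclass
class ApertureMask:
    """Binary raster of a cutout aperture.

    ``values[row, col]`` is 1 where the pixel center lies inside the aperture;
    row index increases with y, column index with x.  ``origin`` is the
    physical (x_cm, y_cm) of the center of pixel (0, 0), so point queries are
    physical rather than index-based.  ``padding_cm`` records the zero margin
    added around the polygon's bounding box (the downstream convolution
    requires at least the kernel half-width of padding).
    """

    values: np.ndarray
    resolution_mm: float
    origin: tuple[float, float]
    padding_cm: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("mask values must be 2-D")
        if not np.all((v == 0) | (v == 1)):
            raise ValueError("mask values must be 0/1")
        self.values = v.astype(np.uint8)

    @property
    def open_pixel_count(self) -> int:
        return int(self.values.sum())


def rasterize(
    shape: CutoutShape, resolution_mm: float = 1.0, padding_cm: float = 0.0
) -> ApertureMask:
    """Rasterize a polygon to a binary mask on the resolution-aligned lattice.

    A pixel is open iff its center lies inside the polygon (even-odd rule).
    Pixel centers sit on integer multiples of the pixel pitch in the cutout
    plane, so translating the polygon by whole pixels translates the mask
    identically.  Centers that fall exactly on an edge are resolved by a
    half-open convention — left/bottom edges included, right/top excluded —
    implemented as an infinitesimal symbolic shift of the test points towards
    (+x, +y).
    """
    if resolution_mm <= 0:
        raise ValueError("resolution must be positive")
    if padding_cm < 0:
        raise ValueError("padding must be non-negative")
    res_cm = resolution_mm / 10.0
    poly = shape.polygon
    minx, miny, maxx, maxy = poly.bounds
    i0 = int(math.floor((minx - padding_cm) / res_cm))
    i1 = int(math.ceil((maxx + padding_cm) / res_cm))
    j0 = int(math.floor((miny - padding_cm) / res_cm))
    j1 = int(math.ceil((maxy + padding_cm) / res_cm))
    xs = np.arange(i0, i1 + 1) * res_cm
    ys = np.arange(j0, j1 + 1) * res_cm
    # the +eps nudge is the half-open boundary rule, not a numerical fudge:
    # it decides ties for centers lying exactly on an edge
    eps = res_cm * 1e-6
    X, Y = np.meshgrid(xs + eps, ys + eps)
    inside = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
    return ApertureMask(
        values=inside.astype(np.uint8),
        resolution_mm=float(resolution_mm),
        origin=(float(xs[0]), float(ys[0])),
        padding_cm=float(padding_cm),
    )


def compute_p2a(shape: CutoutShape) -> float:
    """Perimeter**2 / area of the polygon (dimensionless shape complexity).

    Bounded below by 4*pi (isoperimetric inequality), attained only in the
    circular limit.
    """
    return shape.perimeter_cm**2 / shape.area_cm2


def classify_complexity(p2a: float, cutoff: float = DEFAULT_P2A_CUTOFF) -> str:
    """Classify a P2A value as ``"reliable"`` (p2a <= cutoff) or ``"caution"``.

    The boundary is inclusive.  Values below the isoperimetric bound 4*pi are
    impossible for a simple polygon and signal an upstream bug.
    """
    if not math.isfinite(p2a):
        raise ValueError("P2A must be finite")
    if p2a < P2A_CIRCLE - 1e-9:
        raise ValueError(f"P2A {p2a} below the isoperimetric bound 4*pi")
    return "reliable" if p2a <= cutoff else "caution"
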