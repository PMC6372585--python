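"""Planar geometry primitives shared by every other module.

All coordinates are physical micrometres.  Image pixel ``(row, col)`` maps to
``(y, x)`` with y increasing downward; conversion multiplies by the pixel size
uniformly in both axes.  Contours are closed simple polygons stored in
counter-clockwise orientation (normalized on construction); the implicit edge
from the last vertex back to the first closes the ring.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

#: Distance (µm) within which a query point is classified as on the boundary.
BOUNDARY_TOL_UM = 1e-9


class DegenerateGeometryError(ValueError):
    """Polygon is degenerate: too few vertices, zero area, or self-intersecting."""


class Compartment(enum.Enum):
    MESANGIUM = "mesangium"
    TUFT = "tuft"
    OTHER = "other"


def _signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area of a closed ring given as an (N, 2) vertex array."""
    x = vertices[:, 0]
    y = vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class Contour:
    """A closed simple polygon traced on one section.

    Parameters
    ----------
    vertices : (N, 2) array of float
        Ordered vertex coordinates in µm.  The ring is implicitly closed; do
        not repeat the first vertex.  Orientation is normalized to
        counter-clockwise at construction.
    compartment : Compartment
        Which structure the outline traces (mesangium, whole tuft, other).
    section_index : int
        Zero-based serial-section index the contour was traced on.

    Raises
    ------
    DegenerateGeometryError
        If fewer than 3 distinct vertices, zero area (collinear), or the ring
        self-intersects.
    """

    vertices: np.ndarray
    compartment: Compartment = Compartment.OTHER
    section_index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise DegenerateGeometryError("vertices must be an (N, 2) array")
        if not np.all(np.isfinite(v)):
            raise DegenerateGeometryError("vertices must be finite")
        # drop a duplicated closing vertex if the caller supplied one
        if v.shape[0] >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise DegenerateGeometryError("polygon needs at least 3 vertices")
        area = _signed_area(v)
        if area == 0.0:
            raise DegenerateGeometryError("polygon has zero area (collinear vertices)")
        if area < 0.0:
            v = v[::-1].copy()
        ring = Polygon(v)
        if not ring.is_valid:
            raise DegenerateGeometryError(
                f"polygon is not simple (self-intersecting) on section {self.section_index}"
            )
        if self.section_index < 0:
            raise ValueError("section_index must be non-negative")
        v.setflags(write=False)
        object.__setattr__(self, "vertices", v)

    @property
    def polygon(self) -> Polygon:
        """The contour as a shapely polygon (cached lazily)."""
        poly = getattr(self, "_poly", None)
        if poly is None:
            poly = Polygon(self.vertices)
            object.__setattr__(self, "_poly", poly)
        return poly

    def area(self) -> float:
        return polygon_area(self)

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def transformed(self, t: "RigidTransform2D") -> "Contour":
        return Contour(t.apply(self.vertices), self.compartment, self.section_index)


def polygon_area(contour: Contour) -> float:
    """Area of a contour in µm² by the shoelace formula.

    Strictly positive for any valid :class:`Contour`; invariant under rigid
    transforms of the vertices.
    """
    return abs(_signed_area(contour.vertices))


def point_in_polygon(p, contour: Contour, tol: float = BOUNDARY_TOL_UM) -> str:
    """Classify a point against a contour as ``"inside"``/``"outside"``/``"boundary"``.

    A point within ``tol`` µm of the ring is ``"boundary"``; otherwise the
    even-odd (crossing number) rule decides.
    """
    pt = Point(float(p[0]), float(p[1]))
    poly = contour.polygon
    if poly.exterior.distance(pt) <= tol:
        return "boundary"
    return "inside" if poly.contains(pt) else "outside"


def classify_points(points: np.ndarray, contour: Contour, tol: float = BOUNDARY_TOL_UM):
    """Vectorized point classification.

    Returns
    -------
    inside, boundary : boolean arrays of length N
        ``inside`` is strict interior (excludes boundary points).
    """
    points = np.asarray(points, dtype=float)
    poly = contour.polygon
    inside = shapely.contains_xy(poly, points[:, 0], points[:, 1])
    near = shapely.dwithin(poly.exterior, shapely.points(points), tol)
    return inside & ~near, near


@dataclass(frozen=True)
class RigidTransform2D:
    """Planar rotation + translation (no scaling, no reflection).

    Maps ``x`` to ``R(theta) @ x + t`` where ``R`` is the counter-clockwise
    rotation by ``angle`` radians and ``t = (dx, dy)`` is in µm.
    """

    angle: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.angle) and all(math.isfinite(c) for c in self.translation)):
            raise ValueError("transform parameters must be finite")
        object.__setattr__(self, "translation", (float(self.translation[0]), float(self.translation[1])))

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls(0.0, (0.0, 0.0))

    @property
    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.angle), math.sin(self.angle)
        return np.array([[c, -s], [s, c]])

    def apply(self, pts: np.ndarray) -> np.ndarray:
        """Apply to an (N, 2) array (or a single (2,) point) of µm coordinates."""
        pts = np.asarray(pts, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.matrix.T + np.asarray(self.translation)
        return out[0] if single else out

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        t = self.apply(np.asarray(other.translation))
        ang = math.remainder(self.angle + other.angle, 2 * math.pi)
        return RigidTransform2D(ang, (float(t[0]), float(t[1])))

    def inverse(self) -> "RigidTransform2D":
        t = -(self.matrix.T @ np.asarray(self.translation))
        return RigidTransform2D(-self.angle, (float(t[0]), float(t[1])))

    def is_identity(self, tol: float = 1e-12) -> bool:
        return abs(self.angle) <= tol and all(abs(c) <= tol for c in self.translation)


def apply_transform(t: RigidTransform2D, pts: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`RigidTransform2D.apply`."""
    return t.apply(pts)
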