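"""Aperture geometry for shaped electron fields.

An aperture is the beam-defining cutout in the plane where field sizes are
specified (one fixed SSD plane; no divergence projection is ever applied).
The dose engine only needs the radial boundary function R(theta) -- the
distance from an interior point to the aperture edge along each direction --
so the geometry layer exposes that, plus area/centroid and the equal-area
circle used by the best-fit-circle output workflow.

Polygons must be simple (non-self-intersecting) and star-convex about the
point R(theta) is evaluated from; both are validated.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Point as _ShapelyPoint
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import GeometryError, UnsupportedGeometryError

__all__ = [
    "Aperture",
    "radial_function",
    "boundary_distances",
    "polygon_area_centroid",
    "equal_area_circle",
    "read_polygon_csv",
    "write_polygon_csv",
]

_STAR_CONVEXITY_RAYS = 720


def polygon_area_centroid(
    vertices: Sequence[tuple[float, float]],
) -> tuple[float, tuple[float, float]]:
    """Area (cm^2) and area centroid (cm) of a simple polygon.

    Shoelace formula; the result is independent of vertex winding order.
    Raises :class:`GeometryError` for self-intersecting or degenerate input.
    """
    verts = [(float(x), float(y)) for x, y in vertices]
    if len(verts) < 3:
        raise GeometryError("polygon needs at least 3 vertices")
    poly = _ShapelyPolygon(verts)
    if not poly.is_simple or not poly.is_valid:
        raise GeometryError("polygon is self-intersecting")
    x = np.array([v[0] for v in verts])
    y = np.array([v[1] for v in verts])
    xn = np.roll(x, -1)
    yn = np.roll(y, -1)
    cross = x * yn - xn * y
    signed_area = 0.5 * cross.sum()
    if abs(signed_area) < 1e-12:
        raise GeometryError("degenerate polygon with zero area")
    cx = ((x + xn) * cross).sum() / (6.0 * signed_area)
    cy = ((y + yn) * cross).sum() / (6.0 * signed_area)
    return abs(signed_area), (float(cx), float(cy))


@dataclass(frozen=True)
class Aperture:
    """Beam-defining cutout: circle, rectangle or simple polygon.

    All coordinates and lengths are in cm in the plane of field-size
    definition. ``center`` defaults to (0, 0), the beam central axis.
    Use the :meth:`circle`, :meth:`rectangle`, :meth:`polygon` constructors.
    """

    shape_kind: str
    circle_radius: float | None = None
    length_L: float | None = None
    width_W: float | None = None
    vertices: tuple[tuple[float, float], ...] | None = None
    center: tuple[float, float] = (0.0, 0.0)

    @classmethod
    def circle(cls, radius: float, center: tuple[float, float] = (0.0, 0.0)) -> "Aperture":
        if not radius > 0:
            raise GeometryError(f"circle radius must be positive, got {radius}")
        return cls("circle", circle_radius=float(radius), center=(float(center[0]), float(center[1])))

    @classmethod
    def rectangle(
        cls, length: float, width: float, center: tuple[float, float] = (0.0, 0.0)
    ) -> "Aperture":
        if not (length > 0 and width > 0):
            raise GeometryError(f"rectangle sides must be positive, got {length} x {width}")
        L, W = (length, width) if length >= width else (width, length)
        return cls(
            "rectangle",
            length_L=float(L),
            width_W=float(W),
            center=(float(center[0]), float(center[1])),
        )

    @classmethod
    def polygon(
        cls,
        vertices: Iterable[tuple[float, float]],
        center: tuple[float, float] | None = None,
    ) -> "Aperture":
        """Simple polygon aperture; ``center`` defaults to the beam axis (0, 0).

        Star-convexity about ``center`` is validated on a dense fan of rays so
        that R(theta) is single-valued everywhere it will be evaluated.
        """
        verts = tuple((float(x), float(y)) for x, y in vertices)
        polygon_area_centroid(verts)  # validates simplicity / degeneracy
        c = (0.0, 0.0) if center is None else (float(center[0]), float(center[1]))
        ap = cls("polygon", vertices=verts, center=c)
        _check_star_convex(ap, c)
        return ap

    @property
    def area(self) -> float:
        """Aperture area in cm^2."""
        if self.shape_kind == "circle":
            return math.pi * self.circle_radius**2
        if self.shape_kind == "rectangle":
            return self.length_L * self.width_W
        return polygon_area_centroid(self.vertices)[0]

    @property
    def centroid(self) -> tuple[float, float]:
        """Area centroid in cm (== center for circles and rectangles)."""
        if self.shape_kind == "polygon":
            return polygon_area_centroid(self.vertices)[1]
        return self.center

    def contains(self, point: tuple[float, float], tol: float = 1e-12) -> bool:
        """True if ``point`` is strictly inside the aperture."""
        x, y = point
        cx, cy = self.center
        if self.shape_kind == "circle":
            return math.hypot(x - cx, y - cy) < self.circle_radius - tol
        if self.shape_kind == "rectangle":
            return (
                abs(x - cx) < self.length_L / 2 - tol
                and abs(y - cy) < self.width_W / 2 - tol
            )
        return _ShapelyPoint(x, y).within(_ShapelyPolygon(self.vertices))


def _polygon_ray_distances(
    vertices: np.ndarray, origin: tuple[float, float], thetas: np.ndarray
) -> np.ndarray:
    """Distance from ``origin`` to the polygon boundary along each theta.

    Returns NaN where a ray crosses the boundary zero or more than one time
    (the polygon is not star-convex about the origin along that ray).
    """
    ox, oy = origin
    v1 = vertices
    v2 = np.roll(vertices, -1, axis=0)
    ex = v2[:, 0] - v1[:, 0]
    ey = v2[:, 1] - v1[:, 1]
    wx = v1[:, 0] - ox
    wy = v1[:, 1] - oy

    ux = np.cos(thetas)[:, None]
    uy = np.sin(thetas)[:, None]
    denom = ux * ey[None, :] - uy * ex[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (wx[None, :] * ey[None, :] - wy[None, :] * ex[None, :]) / denom
        s = (wx[None, :] * uy - wy[None, :] * ux) / denom
    # s in [0, 1) half-open so a crossing exactly at a shared vertex is
    # attributed to a single edge
    hit = (np.abs(denom) > 1e-14) & (s >= -1e-12) & (s < 1.0 - 1e-12) & (t > 1e-12)
    n_hits = hit.sum(axis=1)
    t_valid = np.where(hit, t, np.inf)
    out = t_valid.min(axis=1)
    out[n_hits != 1] = np.nan
    return out


def _check_star_convex(aperture: Aperture, origin: tuple[float, float]) -> None:
    verts = np.asarray(aperture.vertices, dtype=float)
    thetas = np.linspace(0.0, 2.0 * math.pi, _STAR_CONVEXITY_RAYS, endpoint=False)
    d = _polygon_ray_distances(verts, origin, thetas)
    bad = np.isnan(d)
    if bad.any():
        theta_bad = float(thetas[np.argmax(bad)])
        raise GeometryError(
            f"polygon is not star-convex about {origin}: ray at theta="
            f"{theta_bad:.4f} rad does not cross the boundary exactly once"
        )


def boundary_distances(
    aperture: Aperture,
    point: tuple[float, float],
    thetas: np.ndarray,
) -> np.ndarray:
    """Distances R(theta) from an interior ``point`` to the aperture boundary.

    This is the radial function the polar dose integral consumes; ``point``
    must lie strictly inside the aperture.
    """
    if not aperture.contains(point):
        raise UnsupportedGeometryError(
            f"point {point} is not strictly inside the aperture; the polar "
            "dose decomposition is only valid for interior points"
        )
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    px, py = point
    cx, cy = aperture.center
    if aperture.shape_kind == "circle":
        dx, dy = px - cx, py - cy
        b = dx * np.cos(thetas) + dy * np.sin(thetas)
        d2 = dx * dx + dy * dy
        return -b + np.sqrt(aperture.circle_radius**2 - d2 + b * b)
    verts = np.asarray(_as_polygon_vertices(aperture), dtype=float)
    d = _polygon_ray_distances(verts, (px, py), thetas)
    if np.isnan(d).any():
        theta_bad = float(thetas[np.argmax(np.isnan(d))])
        raise GeometryError(
            f"polygon is not star-convex about {point}: ray at theta="
            f"{theta_bad:.4f} rad does not cross the boundary exactly once"
        )
    return d


def _as_polygon_vertices(aperture: Aperture) -> tuple[tuple[float, float], ...]:
    if aperture.shape_kind == "polygon":
        return aperture.vertices
    if aperture.shape_kind == "rectangle":
        cx, cy = aperture.center
        a, b = aperture.length_L / 2, aperture.width_W / 2
        return ((cx - a, cy - b), (cx + a, cy - b), (cx + a, cy + b), (cx - a, cy + b))
    raise GeometryError(f"no polygon representation for {aperture.shape_kind}")


def radial_function(aperture: Aperture, theta: float) -> float:
    """Radial distance R(theta) from the aperture's center to its boundary.

    Periodic in theta with period 2*pi. For a rectangle the closed form
    min(L/2|cos|, W/2|sin|) is used; for polygons a ray-edge intersection.
    """
    if not math.isfinite(theta):
        raise GeometryError("theta must be finite")
    if aperture.shape_kind == "circle":
        return aperture.circle_radius
    if aperture.shape_kind == "rectangle":
        a, b = aperture.length_L / 2.0, aperture.width_W / 2.0
        c, s = abs(math.cos(theta)), abs(math.sin(theta))
        if c < 1e-300:
            return b / s
        if s < 1e-300:
            return a / c
        return min(a / c, b / s)
    verts = np.asarray(aperture.vertices, dtype=float)
    d = _polygon_ray_distances(verts, aperture.center, np.array([theta]))
    if np.isnan(d[0]):
        raise GeometryError(
            f"polygon is not star-convex about {aperture.center}: ray at "
            f"theta={theta:.4f} rad does not cross the boundary exactly once"
        )
    return float(d[0])


def equal_area_circle(aperture: Aperture) -> Aperture:
    """Circle with the same area as the aperture, centered at its centroid.

    This is the deterministic 'best-fit circle' used before applying the
    circular-field equivalent-square rule to irregular cutouts. Idempotent
    for circles.
    """
    if aperture.shape_kind == "circle":
        return aperture
    area = aperture.area
    return Aperture.circle(math.sqrt(area / math.pi), center=aperture.centroid)


def read_polygon_csv(path) -> Aperture:
    """Read a polygon aperture from a two-column CSV with header x_cm,y_cm."""
    from .errors import TableFormatError

    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or [c.strip() for c in rows[0][:2]] != ["x_cm", "y_cm"]:
        raise TableFormatError(f"{path}: expected header 'x_cm,y_cm' on line 1")
    verts = []
    for i, row in enumerate(rows[1:], start=2):
        if not row or not "".join(row).strip():
            continue
        try:
            verts.append((float(row[0]), float(row[1])))
        except (ValueError, IndexError) as exc:
            raise TableFormatError(f"{path}: bad vertex on line {i}: {row}") from exc
    return Aperture.polygon(verts)


def write_polygon_csv(aperture: Aperture, path) -> None:
    """Write a polygon aperture as a two-column CSV (header x_cm,y_cm)."""
    verts = _as_polygon_vertices(aperture)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_cm", "y_cm"])
        for x, y in verts:
            w.writerow([repr(x), repr(y)])
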