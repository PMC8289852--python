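"""Planar contour and annulus primitives shared by all unrolling stages.

All geometry lives in image coordinates: ``x`` is the column index
(increasing to the right), ``y`` the row index (increasing downwards),
origin at the top-left corner of a slice, 0-based and continuous
(sub-pixel positions are meaningful).

Orientation of closed contours is canonicalised to "counter-clockwise",
defined once for the whole package as a *positive* shoelace signed area

    A = 1/2 * sum_i (x_i * y_{i+1} - x_{i+1} * y_i)

evaluated in this frame.  For a star-shaped contour this orientation
coincides with increasing azimuth ``atan2(y - o_y, x - o_x)`` about an
interior point ``O``.

Contours are stored *open*: the closing edge from the last point back to
the first is implicit for ``closed=True`` contours.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Iterable

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon


class InvalidContourError(ValueError):
    """Degenerate contour input (zero perimeter or < 3 distinct points)."""


class GeometryError(ValueError):
    """Geometric precondition violated (e.g. inner not inside outer)."""


class ContractError(ValueError):
    """Interface contract violated (mismatched sizes, missing data)."""


# --------------------------------------------------------------------------
# low-level polyline helpers


def as_points(points: Iterable) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidContourError(f"expected an (N, 2) point array, got shape {arr.shape}")
    return arr


def dedupe_points(points: np.ndarray, tol: float = 1e-12, closed: bool = True) -> np.ndarray:
    """Drop consecutive duplicates; for closed input also drop a repeated end point."""
    pts = as_points(points)
    if len(pts) == 0:
        return pts
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > tol
    pts = pts[keep]
    if closed and len(pts) > 1 and np.linalg.norm(pts[0] - pts[-1]) <= tol:
        pts = pts[:-1]
    return pts


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon (positive = canonical CCW)."""
    p = as_points(points)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polyline_length(points: np.ndarray, closed: bool = True) -> float:
    p = as_points(points)
    if len(p) < 2:
        return 0.0
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    total = float(seg.sum())
    if closed:
        total += float(np.linalg.norm(p[0] - p[-1]))
    return total


def contour_perimeter_px(points: np.ndarray) -> int:
    """Contour length in whole pixels: polygonal arc length, rounded.

    Used as the per-contour length L_{h,c}; deliberately independent of the
    sampling density of the point sequence.
    """
    return int(round(polyline_length(points, closed=True)))


def resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to ``n`` points equidistant in arc length.

    The first output point coincides with ``points[0]``; spacing is
    perimeter / n (the closing edge is included).
    """
    pts = dedupe_points(points, closed=True)
    if len(pts) < 3:
        raise InvalidContourError("closed polyline needs >= 3 distinct points")
    loop = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(loop, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise InvalidContourError("zero-perimeter contour")
    t = np.arange(n) * (total / n)
    x = np.interp(t, cum, loop[:, 0])
    y = np.interp(t, cum, loop[:, 1])
    return np.column_stack([x, y])


def resample_open(points: np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline to ``n`` points equidistant in arc length."""
    pts = dedupe_points(points, closed=False)
    if len(pts) < 2:
        raise InvalidContourError("open polyline needs >= 2 distinct points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, cum[-1], n)
    x = np.interp(t, cum, pts[:, 0])
    y = np.interp(t, cum, pts[:, 1])
    return np.column_stack([x, y])


def azimuth(points: np.ndarray, origin) -> np.ndarray:
    """Azimuthal angle about ``origin`` in [0, 2*pi), in the image frame."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    o = np.asarray(origin, dtype=float)
    ang = np.arctan2(p[:, 1] - o[1], p[:, 0] - o[0])
    return np.mod(ang, 2.0 * np.pi)


# --------------------------------------------------------------------------
# domain types


@dataclass
class Contour:
    """An ordered point sequence on one image slice.

    ``points`` is an (N, 2) array of (x, y) positions.  ``slice_index`` is
    the stack height h; ``depth_index`` the relative-depth level c once the
    contour belongs to a re-slicing surface (absent for boundary input).
    """

    points: np.ndarray
    closed: bool = True
    slice_index: int | None = None
    depth_index: int | None = None

    def __post_init__(self) -> None:
        self.points = as_points(self.points)
        if self.closed and len(self.points) < 3:
            raise InvalidContourError("closed contour needs at least 3 points")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def perimeter(self) -> float:
        return polyline_length(self.points, closed=self.closed)

    @property
    def perimeter_px(self) -> int:
        return int(round(self.perimeter))

    @property
    def signed_area(self) -> float:
        if not self.closed:
            raise GeometryError("signed area undefined for open contours")
        return signed_area(self.points)

    def polygon(self) -> Polygon:
        if not self.closed:
            raise GeometryError("open contour has no polygon")
        return Polygon(self.points)


def normalize_contour(raw, n_points: int) -> Contour:
    """Resample to exactly ``n_points`` equidistant points, oriented CCW.

    The output's first point is the (retained) first point of the input, so
    repeated normalisation is stable.  Degenerate input (zero perimeter,
    < 3 distinct points) raises :class:`InvalidContourError`.
    """
    if n_points < 3:
        raise InvalidContourError("n_points must be >= 3")
    if isinstance(raw, Contour):
        pts, h, c = raw.points, raw.slice_index, raw.depth_index
    else:
        pts, h, c = raw, None, None
    pts = dedupe_points(pts, closed=True)
    if len(pts) < 3 or polyline_length(pts, closed=True) <= 0:
        raise InvalidContourError("degenerate contour: need >= 3 distinct points")
    if signed_area(pts) < 0:
        # reverse direction but keep the first point first
        pts = np.vstack([pts[:1], pts[1:][::-1]])
    out = resample_closed(pts, n_points)
    # Refine to a fixed point: one pass spaces points uniformly along the
    # *input* polyline, but the contract is uniform spacing on the output
    # polygon itself.  Re-resampling converges geometrically.
    for _ in range(20):
        new = resample_closed(out, n_points)
        moved = float(np.abs(new - out).max())
        out = new
        if moved < 1e-9:
            break
    return Contour(out, closed=True, slice_index=h, depth_index=c)


@dataclass
class AnnulusSection:
    """Paired inner/outer boundary contours of the tube wall on one slice.

    The inner boundary carries the positive virtual charges, the outer the
    negative ones.  Points exactly on either boundary count as *outside*
    the annulus, which gives field lines a clean termination test.
    """

    inner: Contour
    outer: Contour
    slice_index: int | None = None
    #: if a traced point leaves the admissible region without reaching the
    #: outer boundary, is that a hard failure?  For a closed annulus the
    #: point may dip into the lumen and recover, so no.
    escape_is_failure = False

    def __post_init__(self) -> None:
        if self.inner.n_points != self.outer.n_points:
            raise ContractError(
                f"inner/outer point counts differ: {self.inner.n_points} vs {self.outer.n_points}"
            )
        if not self.outer.polygon().contains(self.inner.polygon()):
            raise GeometryError("inner boundary is not strictly inside the outer boundary")

    @property
    def n_points(self) -> int:
        return self.inner.n_points

    @cached_property
    def _outer_polygon(self) -> Polygon:
        poly = self.outer.polygon()
        shapely.prepare(poly)
        return poly

    @cached_property
    def _inner_polygon(self) -> Polygon:
        poly = self.inner.polygon()
        shapely.prepare(poly)
        return poly

    @cached_property
    def _outer_ring(self) -> LineString:
        return LineString(np.vstack([self.outer.points, self.outer.points[:1]]))

    def contains(self, point) -> bool:
        """Even-odd annulus membership; boundary points are *not* inside."""
        pt = Point(point)
        return bool(self._outer_polygon.contains(pt)) and not bool(
            self._inner_polygon.covers(pt)
        )

    def contains_many(self, points) -> np.ndarray:
        pts = shapely.points(np.asarray(points, dtype=float))
        return shapely.contains(self._outer_polygon, pts) & ~shapely.covers(
            self._inner_polygon, pts
        )

    def reached_outer(self, point) -> bool:
        """True when ``point`` lies on or beyond the outer boundary."""
        return not bool(self._outer_polygon.contains(Point(point)))

    def clip_exit(self, a, b) -> np.ndarray:
        """Intersection of segment a->b with the outer boundary nearest ``a``.

        Falls back to ``b`` if no crossing is found numerically.
        """
        seg = LineString([tuple(a), tuple(b)])
        inter = seg.intersection(self._outer_ring)
        if inter.is_empty:
            return np.asarray(b, dtype=float)
        cands = []
        for geom in getattr(inter, "geoms", [inter]):
            cands.extend(np.asarray(geom.coords))
        cands = np.asarray(cands, dtype=float)
        d = np.linalg.norm(cands - np.asarray(a, dtype=float), axis=1)
        return cands[int(np.argmin(d))]


def pair_boundaries(inner: Contour, outer: Contour, slice_index: int | None = None) -> AnnulusSection:
    """Rotate the outer contour so its start pairs with the inner start.

    The outer index-0 point becomes the outer point nearest (Euclidean) to
    the inner index-0 point; coordinates are never changed, only the cyclic
    start index.  Both contours must already be normalised to the same I.
    """
    if inner.n_points != outer.n_points:
        raise ContractError("pair_boundaries requires equal point counts")
    d = np.linalg.norm(outer.points - inner.points[0], axis=1)
    j = int(np.argmin(d))
    rotated = replace(outer, points=np.roll(outer.points, -j, axis=0))
    if slice_index is None:
        slice_index = inner.slice_index
    return AnnulusSection(inner=inner, outer=rotated, slice_index=slice_index)


def annulus_contains(point, section: AnnulusSection) -> bool:
    """True iff ``point`` is strictly inside the annulus of ``section``."""
    return section.contains(point)


# --------------------------------------------------------------------------
# open (sheet) sections — experimental support for C-shaped thick sheets


@dataclass
class SheetSection:
    """Open inner/outer boundary arcs of a thick sheet (non-closed tube).

    Experimental: exercises the flattening extension path.  The admissible
    region is the simple polygon bounded by the two arcs and the straight
    end caps joining their endpoints.
    """

    inner: Contour
    outer: Contour
    slice_index: int | None = None
    escape_is_failure = True

    def __post_init__(self) -> None:
        if self.inner.closed or self.outer.closed:
            raise ContractError("SheetSection requires open contours")
        if self.inner.n_points != self.outer.n_points:
            raise ContractError("inner/outer point counts differ")
        if not self._region.is_valid or self._region.area <= 0:
            raise GeometryError("sheet arcs do not bound a simple region")

    @property
    def n_points(self) -> int:
        return self.inner.n_points

    @cached_property
    def _region(self) -> Polygon:
        ring = np.vstack([self.inner.points, self.outer.points[::-1]])
        poly = Polygon(ring)
        shapely.prepare(poly)
        return poly

    @cached_property
    def _outer_line(self) -> LineString:
        return LineString(self.outer.points)

    @cached_property
    def _inner_line(self) -> LineString:
        return LineString(self.inner.points)

    def contains(self, point) -> bool:
        return bool(self._region.contains(Point(point)))

    def reached_outer(self, point) -> bool:
        pt = Point(point)
        if self._region.contains(pt):
            return False
        return self._outer_line.distance(pt) < self._inner_line.distance(pt)

    def clip_exit(self, a, b) -> np.ndarray:
        seg = LineString([tuple(a), tuple(b)])
        inter = seg.intersection(self._outer_line)
        if inter.is_empty:
            return np.asarray(b, dtype=float)
        cands = []
        for geom in getattr(inter, "geoms", [inter]):
            cands.extend(np.asarray(geom.coords))
        cands = np.asarray(cands, dtype=float)
        d = np.linalg.norm(cands - np.asarray(a, dtype=float), axis=1)
        return cands[int(np.argmin(d))]
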