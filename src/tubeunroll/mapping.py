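"""Opening, stretching and stacking contours into panoramic views.

Each closed contour of a re-slicing surface is opened at the point whose
azimuth about a fixed rotation axis O is closest to pi (the "left" side
of the tube), densely resampled to its own length L_{h,c} in pixels,
then stretched to the common reference length L (the longest contour in
the volume).  Probing the image stack at all stretched positions yields
one planar panorama per depth level; the stack of panoramas is the
unrolled volume.  The probed source coordinates are retained at full
precision, so mapping panorama cells back to voxels is exact to
rounding — no global inversion of the non-injective stretch is needed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from shapely.geometry import Point, Polygon

from .geometry import ContractError, GeometryError, azimuth, resample_closed
from .meshing import ReslicingSurfaceSet, periodic_spline_resample

logger = logging.getLogger("tubeunroll")


class OpeningError(GeometryError):
    """Rotation axis outside a contour it must open."""


def open_contour(points: np.ndarray, origin, n_out: int | None = None) -> np.ndarray:
    """Open a closed contour at azimuth pi about ``origin``.

    The contour spline is densely resampled to ``n_out`` points (default:
    its perimeter in whole pixels), then cyclically rotated so index 0 is
    the point whose azimuth about ``origin`` is closest to pi; ties break
    to the lowest pre-rotation index.  Column order follows increasing
    azimuth because contours are canonically counter-clockwise.
    """
    pts = np.asarray(points, dtype=float)
    if not Polygon(pts).contains(Point(origin)):
        raise OpeningError(f"rotation axis {tuple(origin)} is not strictly inside the contour")
    if n_out is None:
        closed = np.vstack([pts, pts[:1]])
        n_out = int(round(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()))
    dense = periodic_spline_resample(pts, n_out)
    theta = azimuth(dense, origin)
    j = int(np.argmin(np.abs(theta - np.pi)))  # argmin takes the lowest index on ties
    return np.roll(dense, -j, axis=0)


def reference_length(surfaces: ReslicingSurfaceSet) -> int:
    """Reference length L: the longest contour perimeter in the volume."""
    return int(surfaces.perimeters.max())


def stretch_contour(opened: np.ndarray, L: int) -> np.ndarray:
    """Stretch an opened contour to exactly L points.

    The closed loop is resampled with L points equidistant in arc length
    starting at index 0, so the implied index map i(l) is non-decreasing
    with i(0) = 0.
    """
    opened = np.asarray(opened, dtype=float)
    if len(opened) > L:
        raise ContractError(f"contour has {len(opened)} points, more than L={L}")
    return resample_closed(opened, L)


def stretch_index_map(n_in: int, L: int) -> np.ndarray:
    """Monotone index correspondence i(l) of the linear stretch."""
    return np.minimum((np.arange(L) * n_in) // L, n_in - 1)


@dataclass
class CycloramaVolume:
    """The probed panorama stack plus the coordinate tables for inversion.

    ``values`` holds grey values with layout [c][h][l] (one L-by-H
    panorama per depth level); ``source`` [c][h][l][(x, y)] holds the
    in-slice position each cell probed.  Logical indexing in the package
    docs is G[l, h, c] / S[l, h, c]; the storage order simply puts each
    panorama in a contiguous page.
    """

    values: np.ndarray
    source: np.ndarray
    length: int
    origin: tuple[float, float]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.source = np.asarray(self.source, dtype=float)
        if self.values.ndim != 3:
            raise ContractError("cyclorama values must have shape (C, H, L)")
        if self.source.shape != self.values.shape + (2,):
            raise ContractError("source table must have shape (C, H, L, 2)")
        if self.values.shape[2] != self.length:
            raise ContractError("length does not match the panorama width")

    @property
    def n_levels(self) -> int:
        return self.values.shape[0]

    @property
    def n_slices(self) -> int:
        return self.values.shape[1]

    def column_spacing(self) -> np.ndarray:
        """Per-cell source-point spacing (px) along l — the anisotropic
        pixel-size diagnostic (panorama columns are wider than a source
        pixel wherever a short contour was stretched)."""
        d = np.linalg.norm(np.diff(self.source, axis=2), axis=-1)
        return np.concatenate([d, d[:, :, -1:]], axis=2)

    # -- serialisation -----------------------------------------------------

    def save_tiff(self, path, dtype=None) -> None:
        """Write the panoramas as a multi-page TIFF (one page per level)."""
        import tifffile

        data = self.values
        if dtype is not None:
            info = np.iinfo(dtype) if np.issubdtype(np.dtype(dtype), np.integer) else None
            if info is not None:
                data = np.clip(np.round(data), info.min, info.max)
            data = data.astype(dtype)
        tifffile.imwrite(path, data, photometric="minisblack")

    def save_sidecar(self, path) -> None:
        header = json.dumps({"length": self.length, "origin": list(self.origin),
                             "params": self.params})
        np.savez_compressed(path, source=self.source, values_shape=np.array(self.values.shape),
                            header=np.array(header))

    @classmethod
    def load_sidecar(cls, path) -> tuple[np.ndarray, dict]:
        """Return the source table and the header dict from a sidecar."""
        with np.load(path, allow_pickle=False) as data:
            source = np.asarray(data["source"])
            header = json.loads(str(data["header"]))
        return source, header


def default_origin(surfaces: ReslicingSurfaceSet) -> tuple[float, float]:
    """Centroid of the inner boundary contour of the first slice."""
    centroid = Polygon(surfaces.points[0, 0]).centroid
    return (float(centroid.x), float(centroid.y))


def surface_source_grid(surfaces: ReslicingSurfaceSet, origin=None, L: int | None = None,
                        reverse: bool = False) -> tuple[np.ndarray, tuple[float, float], int]:
    """Open and stretch every contour; return the (C, H, L, 2) source table.

    The rotation axis is constant across slices and depths; it must lie
    strictly inside every inner boundary contour.
    """
    if origin is None:
        origin = default_origin(surfaces)
    origin = (float(origin[0]), float(origin[1]))
    if L is None:
        L = reference_length(surfaces)
    C, H = surfaces.n_levels, surfaces.n_slices
    for h in range(H):
        if not Polygon(surfaces.points[0, h]).contains(Point(origin)):
            logger.warning("rotation axis %s outside inner boundary on slice %d", origin, h)
            raise OpeningError(
                f"rotation axis {origin} is not inside the inner boundary of slice {h}"
            )
    S = np.empty((C, H, L, 2), dtype=float)
    for c in range(C):
        for h in range(H):
            opened = open_contour(surfaces.points[c, h], origin,
                                  int(surfaces.perimeters[c, h]))
            stretched = stretch_contour(opened, L)
            if reverse:
                stretched = np.vstack([stretched[:1], stretched[1:][::-1]])
            S[c, h] = stretched
    return S, origin, L


def probe_volume(volume: np.ndarray, surfaces: ReslicingSurfaceSet, origin=None,
                 L: int | None = None, interp: str = "bilinear", fill: float = 0.0,
                 reverse: bool = False) -> CycloramaVolume:
    """Probe the image stack over all re-slicing surfaces.

    G[l, h, c] is the grey value of slice h at source position S[l, h, c],
    interpolated bilinearly (default) or by nearest neighbour (for label
    volumes).  Out-of-bounds positions receive ``fill``; their count is
    logged.  Slice index h is integral by construction, so interpolation
    is purely in-plane.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ContractError("volume must be a (H, rows, cols) stack")
    if volume.shape[0] != surfaces.n_slices:
        raise ContractError(
            f"volume has {volume.shape[0]} slices but surfaces cover {surfaces.n_slices}"
        )
    if interp not in ("bilinear", "nearest"):
        raise ValueError("interp must be 'bilinear' or 'nearest'")
    order = 1 if interp == "bilinear" else 0
    S, origin, L = surface_source_grid(surfaces, origin, L, reverse)
    C, H = surfaces.n_levels, surfaces.n_slices
    rows, cols = volume.shape[1], volume.shape[2]
    G = np.empty((C, H, L), dtype=float)
    oob = 0
    for h in range(H):
        xs = S[:, h, :, 0]
        ys = S[:, h, :, 1]
        oob += int(np.sum((xs < 0) | (xs > cols - 1) | (ys < 0) | (ys > rows - 1)))
        vals = map_coordinates(volume[h].astype(float), [ys.ravel(), xs.ravel()],
                               order=order, mode="constant", cval=fill)
        G[:, h, :] = vals.reshape(C, L)
    if oob:
        logger.info("probe: %d out-of-bounds positions filled with %s", oob, fill)
    return CycloramaVolume(values=G, source=S, length=L, origin=origin,
                           params={"interp": interp, "fill": fill, "reverse": reverse,
                                   "volume_shape": list(volume.shape),
                                   "out_of_bounds": oob})


def inverse_map(cells, source: np.ndarray | CycloramaVolume, volume_shape,
                cube: int = 1) -> np.ndarray:
    """Map panorama cells back to a binary voxel mask.

    ``cells`` is either a boolean mask with the panorama layout (C, H, L)
    or an iterable of (l, h, c) index triples.  Each cell maps to voxel
    (h, round(S_y), round(S_x)); with ``cube`` > 1 an axis-aligned cube of
    that edge is stamped around each voxel, clipped at the volume border.
    """
    S = source.source if isinstance(source, CycloramaVolume) else np.asarray(source)
    if S.ndim != 4 or S.shape[-1] != 2:
        raise ContractError("source table must have shape (C, H, L, 2)")
    if cube < 1 or cube % 2 == 0:
        raise ValueError("cube edge must be a positive odd integer")
    H, rows, cols = (int(v) for v in volume_shape)
    if S.shape[1] != H:
        raise ContractError("source table slice count does not match volume_shape")
    mask = np.zeros((H, rows, cols), dtype=np.uint8)
    if isinstance(cells, np.ndarray) and cells.dtype == bool:
        if cells.shape != S.shape[:3]:
            raise ContractError(
                f"mask shape {cells.shape} does not match panorama shape {S.shape[:3]}"
            )
        triples = [(l, h, c) for c, h, l in np.argwhere(cells)]
    else:
        triples = [tuple(int(v) for v in cell) for cell in cells]
    half = cube // 2
    for l, h, c in triples:
        x, y = S[c, h, l]
        xi, yi = int(round(x)), int(round(y))
        mask[max(0, h - half): h + half + 1,
             max(0, yi - half): yi + half + 1,
             max(0, xi - half): xi + half + 1] = 1
    return mask
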