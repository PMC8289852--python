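"""Synthetic deformed-tube phantoms with ground truth.

Generates 3D grey-value stacks of a roughly vertical tube whose wall is
bounded by two analytic contours per slice, optionally tapered (radius
linear in h), deformed (sinusoidal lobes, radius(theta) =
R*(1 + a*cos(k*theta + phase(h)))) and twisted (phase linear in h).
Bright disc markers can be embedded at exact (azimuth, relative-depth)
positions inside the wall, so that unrolling can be checked against
known ground truth.  Boundary contours are emitted analytically rather
than re-segmented from the raster, decoupling meshing tests from
segmentation error.

Everything is deterministic for a fixed seed; noise defaults to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .geometry import Contour


class PhantomSpecError(ValueError):
    pass


@dataclass
class Marker:
    """A disc marker at a known azimuth and relative wall depth.

    ``azimuth_deg`` follows the package azimuth convention (angle of
    (x - cx, y - cy) in the image frame); ``depth_fraction`` f in [0, 1]
    places the marker at radius r_in + f * (r_out - r_in) along that
    azimuth; the marker spans slices h_lo..h_hi inclusive.
    """

    azimuth_deg: float
    depth_fraction: float
    h_lo: int
    h_hi: int
    intensity: float = 255.0
    radius: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth_fraction <= 1.0:
            raise PhantomSpecError("depth_fraction must be in [0, 1]")
        if self.h_hi < self.h_lo:
            raise PhantomSpecError("marker height range is empty")


@dataclass
class PhantomSpec:
    """Parameters of a synthetic deformed tube.

    Radius profiles are linear between the start and end values over the
    stack height; the sinusoidal deformation multiplies both radii by
    1 + amplitude*cos(lobes*theta + phase(h)) with phase growing linearly
    to ``twist_rad`` at the last slice.
    """

    H: int = 31
    rows: int = 256
    cols: int = 256
    center: tuple[float, float] | None = None  # (cx, cy); default image centre
    inner_radius: tuple[float, float] = (45.0, 45.0)  # (start, end), px
    outer_radius: tuple[float, float] = (105.0, 105.0)
    deform_amplitude: float = 0.0
    deform_lobes: int = 0
    twist_rad: float = 0.0
    markers: list[Marker] = field(default_factory=list)
    wall_intensity: float = 120.0
    lumen_intensity: float = 30.0
    background_intensity: float = 10.0
    noise_sigma: float = 0.0
    seed: int = 0
    contour_interval: int = 10  # key-slice spacing for emitted contours
    boundary_samples: int = 720  # analytic contour sampling density
    arc_span_deg: float = 360.0  # < 360 gives an open (C-shaped) sheet

    def __post_init__(self) -> None:
        if self.H < 1 or self.rows < 8 or self.cols < 8:
            raise PhantomSpecError("volume dimensions too small")
        if min(self.inner_radius) <= 0:
            raise PhantomSpecError("inner radius must be positive")
        lo = min(o - i for o, i in zip(self.outer_radius, self.inner_radius))
        if lo <= 0:
            raise PhantomSpecError("inner radius must be below outer radius everywhere")
        if not 0.0 <= self.deform_amplitude < 0.5:
            raise PhantomSpecError("deform_amplitude must be in [0, 0.5)")
        for mk in self.markers:
            if mk.h_hi >= self.H:
                raise PhantomSpecError("marker height range exceeds the stack")

    @property
    def centre(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return ((self.cols - 1) / 2.0, (self.rows - 1) / 2.0)

    def phase(self, h: int) -> float:
        if self.H == 1:
            return 0.0
        return self.twist_rad * h / (self.H - 1)

    def _base_radius(self, profile: tuple[float, float], h: int) -> float:
        if self.H == 1:
            return profile[0]
        t = h / (self.H - 1)
        return profile[0] * (1 - t) + profile[1] * t

    def radius(self, boundary: str, theta, h: int) -> np.ndarray:
        """Deformed radius of 'inner'/'outer' at azimuth theta, slice h."""
        base = self._base_radius(
            self.inner_radius if boundary == "inner" else self.outer_radius, h
        )
        theta = np.asarray(theta, dtype=float)
        shape = 1.0 + self.deform_amplitude * np.cos(
            self.deform_lobes * theta + self.phase(h)
        )
        return base * shape

    def boundary_points(self, boundary: str, h: int) -> np.ndarray:
        """Analytic boundary contour on slice h (open iff arc_span < 360)."""
        cx, cy = self.centre
        span = np.deg2rad(self.arc_span_deg)
        closed = self.arc_span_deg >= 360.0
        theta = np.linspace(0.0, span, self.boundary_samples, endpoint=not closed)
        r = self.radius(boundary, theta, h)
        return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])

    @property
    def key_slices(self) -> list[int]:
        keys = set(range(0, self.H, self.contour_interval))
        keys.add(self.H - 1)
        return sorted(keys)


def _render_slice(spec: PhantomSpec, h: int) -> np.ndarray:
    img = np.full((spec.rows, spec.cols), spec.background_intensity, dtype=float)
    outer = spec.boundary_points("outer", h)
    inner = spec.boundary_points("inner", h)
    if spec.arc_span_deg >= 360.0:
        rr, cc = draw_polygon(outer[:, 1], outer[:, 0], shape=img.shape)
        img[rr, cc] = spec.wall_intensity
        rr, cc = draw_polygon(inner[:, 1], inner[:, 0], shape=img.shape)
        img[rr, cc] = spec.lumen_intensity
    else:
        sheet = np.vstack([inner, outer[::-1]])
        rr, cc = draw_polygon(sheet[:, 1], sheet[:, 0], shape=img.shape)
        img[rr, cc] = spec.wall_intensity
    return img


def _marker_centre(spec: PhantomSpec, mk: Marker, h: int) -> tuple[float, float]:
    cx, cy = spec.centre
    theta = np.deg2rad(mk.azimuth_deg)
    r_in = float(spec.radius("inner", theta, h))
    r_out = float(spec.radius("outer", theta, h))
    r = r_in + mk.depth_fraction * (r_out - r_in)
    return (cx + r * np.cos(theta), cy + r * np.sin(theta))


def make_tube(spec: PhantomSpec):
    """Render the phantom volume.

    Returns ``(volume, contours, truth)`` where ``volume`` is a float
    (H, rows, cols) stack, ``contours`` maps each key slice h to an
    (inner, outer) pair of analytic :class:`~tubeunroll.geometry.Contour`
    objects, and ``truth`` is a list of marker ground-truth dicts.
    """
    if spec.arc_span_deg < 360.0:
        raise PhantomSpecError("use make_c_shape for open-boundary phantoms")
    volume = np.empty((spec.H, spec.rows, spec.cols), dtype=float)
    for h in range(spec.H):
        img = _render_slice(spec, h)
        for mk in spec.markers:
            if mk.h_lo <= h <= mk.h_hi:
                x, y = _marker_centre(spec, mk, h)
                wall = float(
                    spec.radius("outer", np.deg2rad(mk.azimuth_deg), h)
                    - spec.radius("inner", np.deg2rad(mk.azimuth_deg), h)
                )
                margin = min(mk.depth_fraction, 1.0 - mk.depth_fraction) * wall
                if mk.radius > margin:
                    raise PhantomSpecError(
                        f"marker at azimuth {mk.azimuth_deg} does not fit inside the wall"
                    )
                rr, cc = draw_disk((y, x), mk.radius, shape=img.shape)
                img[rr, cc] = mk.intensity
        volume[h] = img
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        volume = volume + rng.normal(0.0, spec.noise_sigma, volume.shape)
    contours = {
        h: (
            Contour(spec.boundary_points("inner", h), closed=True, slice_index=h),
            Contour(spec.boundary_points("outer", h), closed=True, slice_index=h),
        )
        for h in spec.key_slices
    }
    truth = [
        {
            "id": idx,
            "azimuth_deg": mk.azimuth_deg,
            "depth_fraction": mk.depth_fraction,
            "h_lo": mk.h_lo,
            "h_hi": mk.h_hi,
            "intensity": mk.intensity,
        }
        for idx, mk in enumerate(spec.markers)
    ]
    return volume, contours, truth


def make_c_shape(spec: PhantomSpec):
    """Render an open, C-shaped thick sheet (experimental).

    Returns ``(volume, contours)`` with per-key-slice (inner, outer)
    *open* arcs.  Exercises the flattening extension path for scrolls and
    sheets of non-uniform thickness.
    """
    if spec.arc_span_deg >= 360.0:
        raise PhantomSpecError("arc_span_deg must be < 360 for a C-shaped sheet")
    if spec.arc_span_deg <= 0:
        raise PhantomSpecError("arc_span_deg must be positive")
    volume = np.stack([_render_slice(spec, h) for h in range(spec.H)])
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        volume = volume + rng.normal(0.0, spec.noise_sigma, volume.shape)
    contours = {
        h: (
            Contour(spec.boundary_points("inner", h), closed=False, slice_index=h),
            Contour(spec.boundary_points("outer", h), closed=False, slice_index=h),
        )
        for h in spec.key_slices
    }
    return volume, contours


def recover_markers(cyclo, truth: list[dict]) -> list[dict]:
    """Locate each ground-truth marker in an unrolled panorama stack.

    For every marker the panorama values are averaged over the marker's
    slice band and the brightest (column, depth-level) cell is taken; the
    recovered azimuth is read off the retained source-coordinate table.
    Returns one dict per marker with ``column``, ``level`` (index c),
    ``depth_fraction`` (c/(C-1)) and ``azimuth_deg``.
    """
    G = cyclo.values  # (C, H, L)
    S = cyclo.source
    C = G.shape[0]
    ox, oy = cyclo.origin
    out = []
    for mk in truth:
        band = G[:, mk["h_lo"]: mk["h_hi"] + 1, :].mean(axis=1)  # (C, L)
        c, l = np.unravel_index(int(np.argmax(band)), band.shape)
        h_mid = (mk["h_lo"] + mk["h_hi"]) // 2
        x, y = S[c, h_mid, l]
        az = float(np.rad2deg(np.mod(np.arctan2(y - oy, x - ox), 2 * np.pi)))
        out.append({
            "id": mk["id"],
            "column": int(l),
            "level": int(c),
            "depth_fraction": c / (C - 1),
            "azimuth_deg": az,
        })
    return out


# --------------------------------------------------------------------------
# presets


def preset(name: str, seed: int = 0) -> PhantomSpec:
    """Named phantom configurations used throughout the test bench.

    ``concentric``
        Straight tube with circular cross sections — the analytic
        identity-limit case.
    ``deformed``
        512x512x61 tube with three sinusoidal lobes (amplitude 0.15) and
        a gentle twist — the stress case for nesting and topology.
    ``markers``
        Straight tube carrying 12 disc markers at relative depths
        {0.25, 0.5, 0.75} x azimuths {0, 90, 180, 270} deg, each in its
        own band of slices — the ground-truth recovery case.
    """
    if name == "concentric":
        return PhantomSpec(H=31, rows=256, cols=256, inner_radius=(45.0, 45.0),
                           outer_radius=(105.0, 105.0), contour_interval=10, seed=seed)
    if name == "deformed":
        return PhantomSpec(H=61, rows=512, cols=512, inner_radius=(90.0, 90.0),
                           outer_radius=(185.0, 185.0), deform_amplitude=0.15,
                           deform_lobes=3, twist_rad=np.deg2rad(40.0),
                           contour_interval=20, seed=seed)
    if name == "markers":
        markers = []
        depths = (0.25, 0.5, 0.75)
        azimuths = (0.0, 90.0, 180.0, 270.0)
        for j, (f, az) in enumerate((f, az) for f in depths for az in azimuths):
            h_lo = 3 + 4 * j
            markers.append(Marker(azimuth_deg=az, depth_fraction=f,
                                  h_lo=h_lo, h_hi=h_lo + 3))
        return PhantomSpec(H=61, rows=400, cols=400, inner_radius=(60.0, 60.0),
                           outer_radius=(150.0, 150.0), markers=markers,
                           contour_interval=20, seed=seed)
    if name == "c-shape":
        return PhantomSpec(H=11, rows=256, cols=256, inner_radius=(50.0, 50.0),
                           outer_radius=(100.0, 100.0), arc_span_deg=180.0,
                           contour_interval=5, seed=seed)
    raise PhantomSpecError(f"unknown preset {name!r}")
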