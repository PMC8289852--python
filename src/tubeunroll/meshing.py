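"""Internal contours at relative depth levels and onion-like surfaces.

Complete field lines on a key slice are each re-represented as a cubic
spline; sampling every line at the same fraction of its own arc length
and fitting a closed periodic spline through the samples yields one
internal contour per relative depth level c/(C-1)*100%.  Key-slice
contours are then interpolated across all H slices with vertical natural
cubic splines through corresponding points, giving a grid of contour
points cont_{h,c} = {p_{i,h,c}} — the re-slicing surface set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.interpolate import CubicSpline

from .geometry import (
    AnnulusSection,
    ContractError,
    dedupe_points,
    polyline_length,
    resample_closed,
)
from .fieldlines import FieldLine

logger = logging.getLogger("tubeunroll")


class ParameterError(ValueError):
    pass


def depth_levels(C: int) -> np.ndarray:
    """Relative depth levels c/(C-1)*100% for c = 0..C-1.

    0% is the inner boundary, 100% the outer; C must be at least 2.
    """
    if int(C) != C or C < 2:
        raise ParameterError("number of depth levels C must be an integer >= 2")
    c = np.arange(int(C), dtype=float)
    return c / (C - 1) * 100.0


@dataclass
class DepthGrid:
    """Depth-level and key-slice bookkeeping for one run.

    ``m`` is the interpolation interval: field lines are only traced on
    every m-th slice; the last slice H-1 is always a key slice so the
    vertical splines never extrapolate.
    """

    C: int
    m: int
    H: int

    def __post_init__(self) -> None:
        if self.C < 2:
            raise ParameterError("C must be >= 2")
        if self.m < 1 or int(self.m) != self.m:
            raise ParameterError("interpolation interval m must be a positive integer")
        if self.H < 1:
            raise ParameterError("H must be >= 1")

    @property
    def levels(self) -> np.ndarray:
        return depth_levels(self.C)

    @property
    def key_slices(self) -> list[int]:
        keys = set(range(0, self.H, self.m))
        keys.add(self.H - 1)
        return sorted(keys)


# --------------------------------------------------------------------------
# spline helpers


def _chord_param(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def sample_line_at_fractions(points: np.ndarray, fracs: np.ndarray) -> np.ndarray:
    """Points at the given fractions of arc length along a line's spline.

    The line's polyline is fitted with a natural cubic spline
    (chord-length parameterised); arc length along the spline is measured
    on a dense subdivision and inverted to locate each fraction.
    """
    pts = dedupe_points(points, closed=False)
    fracs = np.asarray(fracs, dtype=float)
    if len(pts) == 1:
        return np.repeat(pts, len(fracs), axis=0)
    t = _chord_param(pts)
    if len(pts) >= 3:
        spl = CubicSpline(t, pts, axis=0, bc_type="natural")
    else:
        spl = lambda tt: np.column_stack(  # noqa: E731 - linear fallback
            [np.interp(tt, t, pts[:, 0]), np.interp(tt, t, pts[:, 1])]
        )
    td = np.linspace(0.0, t[-1], max(10 * len(pts), 64))
    dense = spl(td)
    s = _chord_param(dense)
    tt = np.interp(fracs * s[-1], s, td)
    return np.atleast_2d(spl(tt))


def periodic_spline_resample(points: np.ndarray, n_out: int) -> np.ndarray:
    """Fit a closed periodic cubic spline through ``points``; resample it
    to ``n_out`` points equidistant in arc length, starting at points[0].
    """
    pts = dedupe_points(points, closed=True)
    if len(pts) < 3:
        raise ContractError("periodic spline needs >= 3 distinct points")
    loop = np.vstack([pts, pts[:1]])
    t = _chord_param(loop)
    spl = CubicSpline(t, loop, axis=0, bc_type="periodic")
    n_dense = max(8 * len(pts), 2 * n_out, 256)
    td = np.linspace(0.0, t[-1], n_dense, endpoint=False)
    dense = spl(td)
    return resample_closed(dense, n_out)


# --------------------------------------------------------------------------
# operations


def internal_contours(lines: list[FieldLine], section: AnnulusSection,
                      C: int, I: int) -> np.ndarray:
    """Internal contours of one key slice at all C depth levels.

    Each surviving line i is sampled at absolute depths c/(C-1)*d_i (arc
    length along its spline); for each level a closed periodic cubic
    spline is fitted through the samples in surviving-index order (the
    loop closes across gaps left by removed lines) and resampled to
    exactly I equidistant points.  Returns an array of shape (C, I, 2).
    """
    if len(lines) < 4:
        raise ContractError("need >= 4 complete field lines")
    if any(not ln.is_complete for ln in lines):
        raise ContractError("internal_contours expects complete lines only")
    fracs = np.arange(C, dtype=float) / (C - 1) if C > 1 else np.zeros(1)
    if C < 2:
        raise ParameterError("C must be >= 2")
    samples = np.stack([sample_line_at_fractions(ln.points, fracs) for ln in lines])
    out = np.empty((C, I, 2), dtype=float)
    for c in range(C):
        out[c] = periodic_spline_resample(samples[:, c, :], I)
    return out


def local_thickness_map(lines_by_slice: dict[int, list[FieldLine]]) -> dict[int, np.ndarray]:
    """Local wall thickness d_i per surviving line, per key slice.

    Returns {h: array of (i, d_i) rows} — a diagnostic table.
    """
    table = {}
    for h, lines in lines_by_slice.items():
        rows = [(ln.index, ln.length) for ln in lines if ln.is_complete]
        table[h] = np.asarray(rows, dtype=float).reshape(-1, 2)
    return table


@dataclass
class ReslicingSurfaceSet:
    """All onion-like surfaces: contour points indexed [c][h][i][(x, y)].

    ``points`` has shape (C, H, I, 2); ``perimeters`` (C, H) holds each
    contour's length L_{h,c} in whole pixels.
    """

    points: np.ndarray
    perimeters: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 4 or self.points.shape[-1] != 2:
            raise ContractError("surface points must have shape (C, H, I, 2)")
        if self.perimeters is None:
            closed = np.concatenate([self.points, self.points[:, :, :1, :]], axis=2)
            seg = np.linalg.norm(np.diff(closed, axis=2), axis=-1)
            self.perimeters = np.round(seg.sum(axis=2)).astype(int)
        else:
            self.perimeters = np.asarray(self.perimeters, dtype=int)
            if self.perimeters.shape != self.points.shape[:2]:
                raise ContractError("perimeters must have shape (C, H)")

    @property
    def n_levels(self) -> int:
        return self.points.shape[0]

    @property
    def n_slices(self) -> int:
        return self.points.shape[1]

    @property
    def n_points(self) -> int:
        return self.points.shape[2]

    def contour(self, h: int, c: int) -> np.ndarray:
        return self.points[c, h]

    def save(self, path, params: dict | None = None) -> None:
        """Single-archive serialisation with a JSON provenance header."""
        header = json.dumps(
            {
                "layout": "points[c][h][i][xy]",
                "C": self.n_levels,
                "H": self.n_slices,
                "I": self.n_points,
                "params": params or {},
            }
        )
        np.savez_compressed(path, points=self.points, perimeters=self.perimeters,
                            header=np.array(header))

    @classmethod
    def load(cls, path) -> tuple["ReslicingSurfaceSet", dict]:
        with np.load(path, allow_pickle=False) as data:
            surf = cls(points=data["points"], perimeters=data["perimeters"])
            header = json.loads(str(data["header"]))
        return surf, header


def interpolate_sections(key_contours: dict[int, np.ndarray], grid: DepthGrid) -> ReslicingSurfaceSet:
    """Fill in contours for every slice with vertical natural cubic splines.

    ``key_contours`` maps key-slice index h to a (C, I, 2) contour array.
    For each (i, c) a natural cubic spline through the key-slice (x(h),
    y(h)) points is evaluated at every integer h in 0..H-1.  Key-slice
    contours are reproduced exactly at their own h; slices outside the
    key range (only possible with incomplete input) are clamped to the
    nearest key.
    """
    keys = sorted(key_contours)
    if not keys:
        raise ContractError("no key-slice contours provided")
    for h in grid.key_slices:
        if h not in key_contours:
            raise ContractError(f"missing contours for key slice {h}")
    shape0 = np.asarray(key_contours[keys[0]]).shape
    stack = []
    for h in keys:
        arr = np.asarray(key_contours[h], dtype=float)
        if arr.shape != shape0:
            raise ContractError("key-slice contour arrays differ in shape")
        stack.append(arr)
    A = np.stack(stack)  # (n_key, C, I, 2)
    hs = np.clip(np.arange(grid.H, dtype=float), keys[0], keys[-1])
    if len(keys) == 1:
        interp = np.repeat(A, grid.H, axis=0)
    else:
        spl = CubicSpline(np.asarray(keys, dtype=float), A, axis=0, bc_type="natural")
        interp = spl(hs)
        # reproduce key slices exactly (no spline round-off)
        for idx, h in enumerate(keys):
            if 0 <= h < grid.H:
                interp[h] = A[idx]
    points = np.transpose(interp, (1, 0, 2, 3))  # (C, H, I, 2)
    return ReslicingSurfaceSet(points=points)
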