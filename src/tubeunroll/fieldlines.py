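"""Virtual electrostatic field-line tracing across an annulus section.

The tube wall on one slice is treated as a 2D capacitor: unit positive
point charges sit on the inner boundary contour, charges of magnitude
``rigidity`` and negative sign on the outer one.  A field line is grown
from each inner boundary point in straight segments of length ``delta``,
each segment following the local field direction summed over a sliding
window of 2w+1 charge pairs centred on the line's start index.  The
physical 1/(4*pi*eps0) prefactor is dropped: the update normalises the
field direction, so only relative charge magnitudes matter.

Lines that fail to reach the outer boundary within ``k_max`` steps are
"stray"; lines that stall near their start (point-scatter variance below
``v_min``) are "collapsed"; both are discarded.  The surviving line
lengths d_i define the local wall thickness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import AnnulusSection, GeometryError, polyline_length

logger = logging.getLogger("tubeunroll")

#: points closer than this to a charge make the 1/r^3 kernel explode
SINGULARITY_RADIUS = 1e-9

COMPLETE = "complete"
STRAY = "stray"
COLLAPSED = "collapsed"


class SingularityError(ArithmeticError):
    """Field evaluated within the guard radius of a point charge."""


class MeshingFailure(RuntimeError):
    """Too few complete field lines to build closed internal contours."""


@dataclass
class FieldLineParams:
    """Tracing parameters.

    n_points
        I, points per boundary contour (charge count per boundary).
    window
        w, half-width of the sliding charge window; 2w+1 <= I.
    delta
        Segment size in pixels; should be below the minimal wall
        thickness (warned otherwise by callers that know the thickness).
    rigidity
        Magnitude of the (negative) outer-boundary charges relative to
        the unit inner charges; higher values stiffen the lines.
    k_max
        Maximum number of segments before a line is declared stray.
    v_min
        Minimum point-scatter variance (px^2); lines below it collapsed.
    """

    n_points: int = 200
    window: int = 15
    delta: float = 2.0
    rigidity: float = 1.0
    k_max: int = 75
    v_min: float = 50.0

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        if self.window < 1:
            raise ValueError("window half-width must be >= 1")
        if 2 * self.window + 1 > self.n_points:
            raise ValueError(
                f"window 2w+1={2 * self.window + 1} exceeds contour size I={self.n_points}"
            )
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.rigidity <= 0:
            raise ValueError("rigidity must be positive")
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if self.v_min < 0:
            raise ValueError("v_min must be >= 0")


@dataclass
class FieldLine:
    """One traced line: its polyline, fate, and length (wall thickness)."""

    index: int
    points: np.ndarray  # (K+1, 2)
    status: str
    length: float | None = None  # d_i, present iff complete
    variance: float = 0.0

    @property
    def n_steps(self) -> int:
        return len(self.points) - 1

    @property
    def is_complete(self) -> bool:
        return self.status == COMPLETE


def window_indices(i: int, w: int, n: int) -> np.ndarray:
    """Cyclic window {(i-w) mod I, ..., i, ..., (i+w) mod I} in order."""
    if 2 * w + 1 > n:
        raise ValueError("window 2w+1 exceeds contour size")
    return np.mod(np.arange(i - w, i + w + 1), n)


def _window(i: int, w: int, n: int, closed: bool) -> np.ndarray:
    if closed:
        return window_indices(i, w, n)
    lo, hi = max(0, i - w), min(n - 1, i + w)
    return np.arange(lo, hi + 1)


def inward_normal(section: AnnulusSection, i: int, delta: float) -> np.ndarray | None:
    """Unit normal at inner point i pointing into the annulus.

    The tangent is the forward difference u_i = p_{i+1,0} - p_{i,0}
    (cyclic); the normal is +/-(u_y, -u_x)/|u| with the sign picked so
    that p_{i,0} + delta * normal lands inside the annulus.  Returns
    ``None`` when neither sign does (wall locally thinner than delta).
    """
    pts = section.inner.points
    n = len(pts)
    if section.inner.closed:
        u = pts[(i + 1) % n] - pts[i]
    else:
        u = pts[min(i + 1, n - 1)] - pts[max(i - 1, 0)] if i == n - 1 else pts[i + 1] - pts[i]
    norm = np.linalg.norm(u)
    if norm == 0:
        return None
    cand = np.array([u[1], -u[0]]) / norm
    for sign in (+1.0, -1.0):
        if section.contains(pts[i] + delta * sign * cand):
            return sign * cand
    return None


def electric_field(point, section: AnnulusSection, i: int, params: FieldLineParams) -> np.ndarray:
    """Windowed two-boundary Coulomb field at ``point`` for line i.

    E = sum_{j in J} (p - p_j)/|p - p_j|^3
        - rigidity * sum_{j in J} (p - p'_j)/|p - p'_j|^3

    with p_j / p'_j the inner/outer boundary charges in the window J
    centred on i.  The electrostatic prefactor is dropped.  Raises
    :class:`SingularityError` within ``SINGULARITY_RADIUS`` of a charge.
    """
    p = np.asarray(point, dtype=float)
    J = _window(i, params.window, section.n_points, section.inner.closed)
    total = np.zeros(2)
    for charges, q in ((section.inner.points[J], 1.0), (section.outer.points[J], -params.rigidity)):
        d = p - charges
        r = np.linalg.norm(d, axis=1)
        if np.any(r < SINGULARITY_RADIUS):
            raise SingularityError(f"field requested within {SINGULARITY_RADIUS} px of a charge")
        total += q * np.sum(d / r[:, None] ** 3, axis=0)
    return total


def _scatter_variance(points: np.ndarray) -> float:
    """Trace-form scatter of the line's points about their centroid.

    V = (1/K) * sum_{k=0..K} |p_k - mean(p)|^2 over all K+1 points.
    """
    if len(points) < 2:
        return 0.0
    k = len(points) - 1
    centred = points - points.mean(axis=0)
    return float(np.sum(centred * centred) / k)


def trace_field_line(section: AnnulusSection, i: int, params: FieldLineParams,
                     clip_final: bool = True) -> FieldLine:
    """Grow field line i from the inner boundary until it exits the wall.

    The first step bypasses the field (it would be singular at the start
    charge) and moves distance ``delta`` along the inward boundary normal;
    every later step moves ``delta`` along the field direction evaluated
    at the previous point.  A line is complete once a point lands on or
    beyond the outer boundary; its final segment is then clipped at the
    exact boundary crossing (disable with ``clip_final`` to reproduce the
    K*delta length convention) and d_i is the resulting polyline length.
    """
    p0 = section.inner.points[i]
    normal = inward_normal(section, i, params.delta)
    if normal is None:
        # cannot even take the first step: treated as collapsed at start
        return FieldLine(i, p0[None, :].copy(), COLLAPSED, None, 0.0)
    pts = [p0, p0 + params.delta * normal]
    status = None
    if section.reached_outer(pts[-1]):
        status = COMPLETE
    else:
        for _k in range(2, params.k_max + 1):
            try:
                E = electric_field(pts[-1], section, i, params)
            except SingularityError:
                status = STRAY
                break
            mag = np.linalg.norm(E)
            if not np.isfinite(mag) or mag < 1e-300:
                status = STRAY
                break
            p = pts[-1] + params.delta * E / mag
            pts.append(p)
            if section.reached_outer(p):
                status = COMPLETE
                break
            if section.escape_is_failure and not section.contains(p):
                status = STRAY
                break
        else:
            status = STRAY
    pts = np.asarray(pts)
    variance = _scatter_variance(pts)
    length = None
    if status == COMPLETE:
        if clip_final and len(pts) >= 2:
            pts[-1] = section.clip_exit(pts[-2], pts[-1])
        length = polyline_length(pts, closed=False)
    if variance < params.v_min:
        status = COLLAPSED
        length = None
    return FieldLine(i, pts, status, length, variance)


def trace_all(section: AnnulusSection, params: FieldLineParams,
              clip_final: bool = True) -> list[FieldLine]:
    """Trace all I lines; keep complete ones in increasing index order.

    Stray and collapsed lines are discarded (counts are logged).  Fewer
    than 4 survivors cannot support a closed cubic contour and raise
    :class:`MeshingFailure`.
    """
    if params.n_points != section.n_points:
        raise ValueError(
            f"params.n_points={params.n_points} does not match section I={section.n_points}"
        )
    lines = [trace_field_line(section, i, params, clip_final) for i in range(section.n_points)]
    complete = [ln for ln in lines if ln.is_complete]
    n_stray = sum(ln.status == STRAY for ln in lines)
    n_collapsed = sum(ln.status == COLLAPSED for ln in lines)
    logger.info(
        "slice %s: %d complete, %d stray, %d collapsed field lines",
        section.slice_index, len(complete), n_stray, n_collapsed,
    )
    if len(complete) < 4:
        raise MeshingFailure(
            f"only {len(complete)} complete field lines on slice {section.slice_index}; "
            "need >= 4 to fit a closed cubic contour"
        )
    return complete


# --------------------------------------------------------------------------
# diagnostics


def lines_to_json(lines: list[FieldLine]) -> list[dict]:
    """JSON-serialisable dump of traced lines for visual QA."""
    return [
        {
            "index": ln.index,
            "status": ln.status,
            "length": ln.length,
            "variance": ln.variance,
            "points": np.asarray(ln.points).tolist(),
        }
        for ln in lines
    ]


def save_overlay(path, image: np.ndarray, section: AnnulusSection,
                 lines: list[FieldLine]) -> None:
    """Write a PNG of the slice with boundaries and field lines overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(image, cmap="gray", interpolation="nearest")
    for contour, color in ((section.inner, "tab:red"), (section.outer, "tab:blue")):
        loop = np.vstack([contour.points, contour.points[:1]]) if contour.closed else contour.points
        ax.plot(loop[:, 0], loop[:, 1], color=color, lw=1.0)
    for ln in lines:
        ax.plot(ln.points[:, 0], ln.points[:, 1], color="yellow", lw=0.5)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
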