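"""Shared fixtures: analytic sections and tracing parameters.

All fixtures are deterministic; phantoms are generated in memory at test
time (no stored image data).
"""

from __future__ import annotations

import numpy as np
import pytest

import tubeunroll as tu


def circle_points(radius: float, center=(0.0, 0.0), n: int = 400) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(th),
                            center[1] + radius * np.sin(th)])


def ellipse_points(a: float, b: float, center=(0.0, 0.0), n: int = 400) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + a * np.cos(th),
                            center[1] + b * np.sin(th)])


def make_section(inner_pts, outer_pts, n_points: int = 200) -> tu.AnnulusSection:
    inner = tu.normalize_contour(inner_pts, n_points)
    outer = tu.normalize_contour(outer_pts, n_points)
    return tu.pair_boundaries(inner, outer)


CENTER = (50.0, 50.0)


@pytest.fixture(scope="session")
def concentric_section() -> tu.AnnulusSection:
    """Concentric circles of radii 20 / 40, I = 200 — the analytic case."""
    return make_section(circle_points(20, CENTER), circle_points(40, CENTER), 200)


@pytest.fixture(scope="session")
def analytic_params() -> tu.FieldLineParams:
    """Tracing parameters matched to the 20-px analytic annulus.

    v_min is set well below d^2/12 ~ 33 px^2 (the scatter of a straight
    20-px line) so that no genuine line is rejected as collapsed.
    """
    return tu.FieldLineParams(n_points=200, window=15, delta=2.0,
                              rigidity=1.0, k_max=75, v_min=1.0)


@pytest.fixture(scope="session")
def concentric_lines(concentric_section, analytic_params):
    return tu.trace_all(concentric_section, analytic_params)
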